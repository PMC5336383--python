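"""Cohort mortality tables and synthetic data generation.

Real analyses of this kind run on Human Mortality Database (HMD) style
tables of age-specific death counts D(x) and person-years of exposure E(x),
one table per birth cohort (or calendar year) per sex.  HMD data require
registration, so this module both reads that layout and generates
statistically equivalent synthetic tables from known GGM parameters:
deterministic exposures following cohort survivorship under the marginal
hazard, and Poisson death counts with intensity E(x) * mu(x + 1/2) -- the
exact generative model assumed by the Poisson likelihood used for fitting.

A Monte Carlo lifetime simulator is also provided; it is the independent
oracle against which the matrix-model longevity moments are checked.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .ggm import FrailtyDiscretization, GGMParams, gm_hazard, marginal_hazard

__all__ = [
    "MortalityData",
    "generate_poisson_cohort",
    "simulate_lifetimes",
    "write_mortality_table",
    "read_mortality_table",
    "read_hmd_1x1",
]

_CANONICAL_COLUMNS = ["cohort", "sex", "age", "deaths", "exposure"]
_SEXES = {"female", "male", "total"}


@dataclass
class MortalityData:
    """A per-cohort table of (age, death count, exposure).

    Ages are contiguous integers; rows with zero exposure must have zero
    deaths.  ``meta`` carries free-form provenance (generator parameters,
    seed) written as header comments by :func:`write_mortality_table`.
    """

    cohort_label: str
    sex: str
    age: np.ndarray
    deaths: np.ndarray
    exposure: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {sorted(_SEXES)}, got {self.sex!r}")
        self.age = np.asarray(self.age, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        if self.age.size == 0:
            raise ValueError("mortality table has no rows")
        if not (self.age.size == self.deaths.size == self.exposure.size):
            raise ValueError("age, deaths, exposure must have equal length")
        if np.any(np.diff(self.age) != 1):
            raise ValueError("ages must be strictly increasing contiguous integers")
        if np.any(self.deaths < 0) or np.any(self.exposure < 0):
            raise ValueError("deaths and exposures must be nonnegative")
        bad = (self.exposure == 0) & (self.deaths > 0)
        if np.any(bad):
            age = self.age[bad][0]
            raise ValueError(f"age {age}: positive deaths with zero exposure")

    def __len__(self) -> int:
        return self.age.size

    def restrict(self, min_age: int, max_age: int | None = None) -> "MortalityData":
        """Rows with ``min_age <= age`` (and ``<= max_age`` if given)."""
        keep = self.age >= min_age
        if max_age is not None:
            keep &= self.age <= max_age
        if not keep.any():
            raise ValueError(f"no rows in age range [{min_age}, {max_age}]")
        return MortalityData(
            self.cohort_label, self.sex,
            self.age[keep], self.deaths[keep], self.exposure[keep],
            dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cohort": self.cohort_label,
                "sex": self.sex,
                "age": self.age,
                "deaths": self.deaths,
                "exposure": self.exposure,
            }
        )


def generate_poisson_cohort(
    params: GGMParams,
    n0: float = 1e6,
    start_age: int | None = None,
    n_ages: int = 70,
    seed: int | np.random.Generator | None = None,
    cohort_label: str = "synthetic",
    sex: str = "total",
) -> MortalityData:
    """Generate an HMD-style cohort table from known GGM parameters.

    Exposures are deterministic expected person-years: ``n0`` individuals
    alive at the starting age are thinned by the marginal-hazard
    survivorship ``l(x) = exp(-int_0^x mu(s) ds)`` (computed by adaptive
    quadrature of the marginal hazard), and E(x) is the trapezoid of l at
    the interval endpoints.  Death counts are then drawn as
    ``D(x) ~ Poisson(E(x) * mu(x + 1/2))``.

    ``start_age`` defaults to ``params.start_age``; ages in the returned
    table are calendar ages ``start_age .. start_age + n_ages - 1``.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if n_ages < 2:
        raise ValueError("n_ages must be >= 2")
    if start_age is None:
        start_age = params.start_age
    rng = np.random.default_rng(seed)

    # Cumulative marginal hazard at model ages 0..n_ages (closed form exists
    # but quadrature keeps this independent of the hazard's algebraic form).
    x_grid = np.arange(n_ages + 1, dtype=float)
    cum = np.empty_like(x_grid)
    cum[0] = 0.0
    for i in range(1, x_grid.size):
        piece, _ = quad(lambda t: marginal_hazard(t, params), x_grid[i - 1], x_grid[i])
        cum[i] = cum[i - 1] + piece
    survivorship = np.exp(-cum)

    exposure = n0 * 0.5 * (survivorship[:-1] + survivorship[1:])
    mu_mid = marginal_hazard(x_grid[:-1] + 0.5, params)
    deaths = rng.poisson(exposure * mu_mid).astype(float)

    ages = start_age + np.arange(n_ages)
    meta = {
        "generator": "generate_poisson_cohort",
        "a": params.a, "b": params.b, "c": params.c, "gamma": params.gamma,
        "model_start_age": start_age, "n0": n0,
    }
    return MortalityData(cohort_label, sex, ages, deaths, exposure, meta)


def simulate_lifetimes(
    params: GGMParams,
    frailty: FrailtyDiscretization,
    n: int,
    omega: int = 150,
    seed: int | np.random.Generator | None = None,
    return_labels: bool = False,
):
    """Simulate ``n`` discrete ages-at-death from the age x frailty chain.

    Each individual draws a frailty class from the mixing distribution, then
    survives age class j with probability ``exp(-mu(z_i, j-1))``, exactly
    the survival probabilities of the matrix model.  The returned value per
    individual is the number of age classes attained (absorption time
    counting the starting class); the last class ``omega`` is terminal.

    Sampling draws each lifetime directly from the per-class absorption-time
    distribution implied by those survival probabilities (inverse cdf, one
    uniform per individual) -- the same law as sequential Bernoulli
    survival, vectorized.

    With ``return_labels=True`` also returns the frailty class index of
    each individual (needed for the empirical variance decomposition).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    g = frailty.g

    # p[i, j] = survival probability of class i through age class j+1
    ages = np.arange(omega - 1, dtype=float)
    p = np.exp(-gm_hazard(ages[None, :], frailty.z[:, None], params))

    # Survivorship to each age class (l[:, 0] = 1), then absorption pmf:
    # P(eta = j) = l_j * (1 - p_j) for j < omega, P(eta = omega) = l_omega.
    l = np.cumprod(np.hstack([np.ones((g, 1)), p]), axis=1)
    pmf = np.hstack([l[:, :-1] * (1.0 - p), l[:, -1:]])
    cdf = np.cumsum(pmf, axis=1)
    cdf[:, -1] = 1.0

    labels = rng.choice(g, size=n, p=frailty.pi)
    u = rng.random(n)
    lifetimes = np.empty(n, dtype=int)
    for i in range(g):
        mask = labels == i
        if mask.any():
            lifetimes[mask] = np.searchsorted(cdf[i], u[mask]) + 1
    if return_labels:
        return lifetimes, labels
    return lifetimes


def write_mortality_table(data: MortalityData, destination) -> None:
    """Write a table in the canonical tab-separated format.

    Header comments (lines starting with ``#``) record the generator
    parameters and seed from ``data.meta``.
    """
    df = data.to_frame()
    buf = io.StringIO()
    for key, value in data.meta.items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    text = buf.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def read_mortality_table(source) -> MortalityData:
    """Read one cohort table in the canonical TSV format.

    Raises a parse error naming the offending line for malformed rows,
    negative counts or non-contiguous ages.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        text = Path(source).read_text()
        name = str(source)

    meta = {}
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
        else:
            break
    body = "\n".join(lines[body_start:])
    if not body.strip():
        raise ValueError(f"{name}: empty mortality table")

    try:
        df = pd.read_csv(io.StringIO(body), sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{name}: cannot parse table: {exc}") from exc
    missing = [c for c in _CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{name}: empty mortality table")

    for col in ("age", "deaths", "exposure"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            # +2: one for the header line, one for 0- vs 1-based
            line_no = body_start + int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(f"{name}, line {line_no}: non-numeric {col!r}")
        df[col] = pd.to_numeric(df[col])

    try:
        return MortalityData(
            cohort_label=str(df["cohort"].iloc[0]),
            sex=str(df["sex"].iloc[0]),
            age=df["age"].to_numpy(),
            deaths=df["deaths"].to_numpy(),
            exposure=df["exposure"].to_numpy(),
            meta=meta,
        )
    except ValueError as exc:
        raise ValueError(f"{name}: {exc}") from exc


def read_hmd_1x1(deaths_source, exposures_source, sex: str = "total") -> list[MortalityData]:
    """Read paired HMD 1x1 Deaths and Exposures files (cohort or period layout).

    The HMD layout has a free-text preamble, a header row with columns
    ``Year  Age  Female  Male  Total``, and an open age group ``110+`` which
    is dropped (at omega = 150 with certain death in the last class the tail
    beyond 110 is negligible).  Returns one :class:`MortalityData` per year
    (cohort) present in both files.
    """
    col = sex.capitalize()
    if sex not in _SEXES:
        raise ValueError(f"sex must be one of {sorted(_SEXES)}, got {sex!r}")

    def _load(source):
        if hasattr(source, "read"):
            lines = source.read().splitlines()
        else:
            lines = Path(source).read_text().splitlines()
        header_idx = next(
            (i for i, ln in enumerate(lines) if ln.split()[:2] == ["Year", "Age"]),
            None,
        )
        if header_idx is None:
            raise ValueError("not an HMD 1x1 file: no 'Year Age ...' header found")
        df = pd.read_csv(
            io.StringIO("\n".join(lines[header_idx:])),
            sep=r"\s+",
            na_values=["."],
        )
        df = df[df["Age"] != "110+"].copy()
        df["Age"] = df["Age"].astype(int)
        return df

    deaths = _load(deaths_source)
    exposures = _load(exposures_source)
    merged = deaths.merge(exposures, on=["Year", "Age"], suffixes=("_d", "_e"))

    tables = []
    for year, grp in merged.groupby("Year"):
        grp = grp.sort_values("Age").dropna(subset=[f"{col}_d", f"{col}_e"])
        if grp.empty:
            continue
        tables.append(
            MortalityData(
                cohort_label=str(year),
                sex=sex,
                age=grp["Age"].to_numpy(),
                deaths=grp[f"{col}_d"].to_numpy(),
                exposure=grp[f"{col}_e"].to_numpy(),
                meta={"source": "hmd_1x1"},
            )
        )
    if not tables:
        raise ValueError("no usable (deaths, exposure) rows in HMD input")
    return tables
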