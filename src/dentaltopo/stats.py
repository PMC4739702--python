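"""Statistical comparison of OPCR treatments across species.

The mesh-based 3D-OPCR algorithm was validated against the legacy
raster-DEM OPCR on second mandibular molars (M2s) of four cercopithecoid
species (n = 36: Cercocebus atys 7, Cercopithecus mitis 10, Colobus
guereza 10, Theropithecus gelada 9).  This module reproduces that
analysis layer: one-way ANOVA with a species factor, Tukey HSD pairwise
comparisons (Tukey-Kramer for the unbalanced groups, matching SPSS), and
ordinary least squares of per-specimen dOPCR = 3D-OPCR - DEM-OPCR on the
raw treatments.

The raw per-specimen table is not redistributable, but the published
per-species summary statistics (mean and SD of DEM-OPCR, 3D-OPCR, and
dOPCR) fully determine every statistic of the analysis: ANOVA needs only
group moments, Tukey needs group means plus the pooled within-group
variance, and because dOPCR is a linear combination of the two
treatments, the three SDs per species pin down the within-species
covariance, which (with the group means) fixes the pooled regression
slope, intercept, and R^2.  :func:`synthesize_specimen_table` therefore
generates a synthetic per-specimen table whose per-species sample
moments match the packaged summary exactly; any statistic of those
moments computed from it is exact, not approximate.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05


@dataclass
class AnovaResult:
    """One-way ANOVA decomposition; F = ms_between / ms_within."""

    F: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    p: float


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p: float


def species_summary() -> pd.DataFrame:
    """Published per-species OPCR summary statistics (the packaged table)."""
    ref = importlib.resources.files("dentaltopo") / "data" / "opcr_species_summary.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_specimen_table(source) -> pd.DataFrame:
    """Load a per-specimen TSV/CSV with columns specimen, species,
    dem_opcr, opcr3d.  delta_opcr is always recomputed, never trusted
    from file."""
    df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"specimen", "species", "dem_opcr", "opcr3d"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    df = df.copy()
    df["delta_opcr"] = df["opcr3d"] - df["dem_opcr"]
    return df


def synthesize_specimen_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic per-specimen table moment-matched to the packaged summary.

    For each species, standard-normal draws are empirically whitened
    (exact sample mean 0, sample covariance I with ddof=1) and recolored
    to the species' target mean vector and covariance matrix, so the
    synthetic sample's per-species means, SDs, and DEM/3D covariance
    equal the published values to machine precision regardless of seed.
    The within-species covariance is recovered from the dOPCR SD via
    Var(d) = Var(3D) + Var(DEM) - 2 Cov(3D, DEM).
    """
    rng = np.random.default_rng(seed)
    summary = species_summary()
    rows = []
    for _, s in summary.iterrows():
        n = int(s["n"])
        var_dem = s["dem_sd"] ** 2
        var_td = s["opcr3d_sd"] ** 2
        var_delta = s["delta_sd"] ** 2
        cov = (var_td + var_dem - var_delta) / 2.0
        target = np.array([[var_dem, cov], [cov, var_td]])
        mean = np.array([s["dem_mean"], s["opcr3d_mean"]])
        x = rng.standard_normal((n, 2))
        xc = x - x.mean(axis=0)
        sample_cov = xc.T @ xc / (n - 1)
        white = xc @ np.linalg.inv(np.linalg.cholesky(sample_cov)).T
        y = white @ np.linalg.cholesky(target).T + mean
        for i in range(n):
            rows.append({
                "specimen": f"{s['species'].split()[0][:4].lower()}_{i + 1:02d}",
                "species": s["species"],
                "dem_opcr": y[i, 0],
                "opcr3d": y[i, 1],
            })
    df = pd.DataFrame(rows)
    df["delta_opcr"] = df["opcr3d"] - df["dem_opcr"]
    return df


def one_way_anova(values, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA of ``values`` on the ``groups`` factor."""
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    grand = values.mean()
    ssb = ssw = 0.0
    for g in labels:
        x = values[groups == g]
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        ssb += len(x) * (x.mean() - grand) ** 2
        ssw += ((x - x.mean()) ** 2).sum()
    dfb = len(labels) - 1
    dfw = len(values) - len(labels)
    msb = ssb / dfb
    msw = ssw / dfw
    F = msb / msw
    p = float(scipy.stats.f.sf(F, dfb, dfw))
    return AnovaResult(float(F), dfb, dfw, float(msb), float(msw), p)


def tukey_hsd(values, groups, alpha: float = ALPHA) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (Tukey-Kramer when unbalanced).

    Returns a DataFrame with columns group1, group2, mean_diff (absolute),
    p_adj, significant (p_adj < alpha).
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    # pairwise_tukeyhsd orders comparisons as upper-triangle combinations
    # of the sorted unique group labels
    from itertools import combinations
    pairs = [(str(a), str(b)) for a, b in combinations(res.groupsunique, 2)]
    return pd.DataFrame({
        "group1": [p[0] for p in pairs],
        "group2": [p[1] for p in pairs],
        "mean_diff": np.abs(res.meandiffs),
        "p_adj": res.pvalues,
        "significant": res.pvalues < alpha,
    })


def linear_fit(x, y) -> LinearFit:
    """OLS fit y = m x + b with R^2 and the slope-t two-sided p value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("linear fit needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = scipy.stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2), float(res.pvalue))


def validation_report(df: pd.DataFrame) -> dict:
    """Run the full treatment comparison on a per-specimen table.

    Returns a dict with per-species descriptives, ANOVAs for each OPCR
    treatment and for dOPCR, Tukey HSD tables, and the dOPCR regressions
    on each treatment.
    """
    out: dict = {}
    desc = df.groupby("species").agg(
        n=("specimen", "size"),
        dem_mean=("dem_opcr", "mean"), dem_sd=("dem_opcr", "std"),
        opcr3d_mean=("opcr3d", "mean"), opcr3d_sd=("opcr3d", "std"),
        delta_mean=("delta_opcr", "mean"), delta_sd=("delta_opcr", "std"),
    ).reset_index()
    out["descriptives"] = desc
    for col, key in (("dem_opcr", "dem"), ("opcr3d", "td"), ("delta_opcr", "delta")):
        out[f"anova_{key}"] = one_way_anova(df[col], df["species"])
        out[f"tukey_{key}"] = tukey_hsd(df[col], df["species"])
    out["fit_delta_on_td"] = linear_fit(df["opcr3d"], df["delta_opcr"])
    out["fit_delta_on_dem"] = linear_fit(df["dem_opcr"], df["delta_opcr"])
    return out
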