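"""Co-culture rescue analysis: GFP/SRB expected-vs-measured growth.

GFP-labeled knockout (KO) cells are co-cultured with unlabeled wild-type
(WT) cells at varying seeding ratios.  Total biomass is read from
sulforhodamine B (SRB) absorbance and the KO compartment from GFP
fluorescence.  In KO mono-cultures GFP and SRB measure the same
quantity, which provides a linear calibration between the two readouts.
Applying that calibration to a co-culture's SRB signal, scaled by the KO
seeding fraction, predicts the GFP signal expected if WT and KO cells
grew identically; measured GFP above that expectation means the KO
compartment expanded at the expense of its WT neighbors (metabolic
rescue through gap junctions).

The module also carries two intracellular-pH summaries used in the
Na+/H+-exchanger experiments: the post-acid-load pH recovery slope, and
the mode-offset spread of a resting-pH distribution.  pH traces enter
already calibrated to pH units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "GrowthPlate",
    "GfpSrbCalibration",
    "RescueResult",
    "RatioResult",
    "calibrate_gfp_srb",
    "expected_gfp",
    "enrichment_test",
    "phi_recovery_rate",
    "distribution_offset_to_mode",
]

PLATE_COLUMNS = ("well_id", "day", "seeding_ko", "seeding_wt", "gfp", "srb", "condition")


@dataclass
class GrowthPlate:
    """Well-level GFP/SRB readings over days, with seeding composition.

    ``wells`` must contain the columns well_id, day, seeding_ko,
    seeding_wt, gfp, srb, condition (one of ko_mono / wt_mono / co).
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PLATE_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"growth plate missing columns {sorted(missing)}")
        w = self.wells
        if (w["seeding_ko"] < 0).any() or (w["seeding_wt"] < 0).any():
            raise ValueError("seeding counts must be >= 0")
        if (w["day"] < 0).any():
            raise ValueError("day must be >= 0")
        if not (w["condition"] == "ko_mono").any():
            raise ValueError("at least one KO mono-culture well required for calibration")

    def seeding_ratios(self) -> list[tuple[int, int]]:
        pairs = self.wells[["seeding_ko", "seeding_wt"]].drop_duplicates()
        return [tuple(map(int, row)) for row in pairs.itertuples(index=False)]


class GfpSrbCalibration(NamedTuple):
    """Linear-through-origin mapping GFP = slope * SRB from KO mono-cultures."""

    slope: float
    residual_sd: float
    n_wells: int
    residual_by_day: pd.Series

    def __call__(self, srb) -> np.ndarray:
        return self.slope * np.asarray(srb, dtype=float)


def calibrate_gfp_srb(plate: GrowthPlate) -> GfpSrbCalibration:
    """Fit the GFP = g * SRB calibration on KO mono-culture wells.

    Pooled over days; requires at least three KO mono-culture wells
    spanning at least two distinct days.  The per-day mean residual is
    returned as a diagnostic so calibration nonlinearity is visible.
    """
    ko = plate.wells[plate.wells["condition"] == "ko_mono"]
    if len(ko) < 3:
        raise ValueError(f"need >= 3 KO mono-culture wells, got {len(ko)}")
    if ko["day"].nunique() < 2:
        raise ValueError("KO mono-culture wells must span >= 2 days")
    srb = ko["srb"].to_numpy(dtype=float)
    gfp = ko["gfp"].to_numpy(dtype=float)
    denom = float(np.dot(srb, srb))
    if denom <= 0 or np.ptp(srb) == 0:
        raise ValueError("degenerate SRB spread in calibration wells")
    slope = float(np.dot(srb, gfp) / denom)
    if slope <= 0:
        raise ValueError(f"non-positive calibration slope {slope:.3g}")
    resid = gfp - slope * srb
    resid_sd = float(np.std(resid, ddof=1))
    by_day = pd.Series(resid, index=ko["day"].to_numpy()).groupby(level=0).mean()
    return GfpSrbCalibration(slope, resid_sd, len(ko), by_day)


def expected_gfp(
    srb_trajectory, seeding_fraction_ko: float, calibration: GfpSrbCalibration
) -> np.ndarray:
    """Expected GFP under the null of identical WT/KO growth.

    The calibration converts total biomass (SRB) into GFP-equivalent
    units; scaling by the KO seeding fraction (e.g. 0.5 for a 1:1
    co-culture) gives the KO compartment's expected share.
    """
    if calibration is None:
        raise ValueError("missing calibration")
    if not (0.0 <= seeding_fraction_ko <= 1.0):
        raise ValueError("seeding_fraction_ko must lie in [0, 1]")
    return calibration(srb_trajectory) * seeding_fraction_ko


@dataclass
class RatioResult:
    """Measured-vs-expected outcome for one seeding ratio."""

    seeding_ko: int
    seeding_wt: int
    days: np.ndarray
    measured_gfp: np.ndarray  # mean over replicate wells, per day
    expected_gfp: np.ndarray
    enrichment_ratio: float  # endpoint measured / expected
    p_value: float | None
    significant: bool


@dataclass
class RescueResult:
    per_ratio: list[RatioResult]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seeding_ko": [r.seeding_ko for r in self.per_ratio],
                "seeding_wt": [r.seeding_wt for r in self.per_ratio],
                "enrichment_ratio": [r.enrichment_ratio for r in self.per_ratio],
                "p_value": [r.p_value for r in self.per_ratio],
                "significant": [r.significant for r in self.per_ratio],
            }
        )


def _degenerate_p(long: pd.DataFrame) -> float | None:
    """Zero-residual guard: with noiseless wells the F statistic is 0/0."""
    resid = long.groupby(["kind", "day"])["y"].transform("mean")
    if float(np.var(long["y"] - resid)) > 1e-18:
        return None
    means = long.groupby("kind")["y"].mean()
    return 1.0 if abs(means.max() - means.min()) < 1e-9 else 0.0


def _ratio_test_anova(long: pd.DataFrame) -> float:
    """Two-factor test (trajectory kind x day) on per-well log GFP/SRB ratios.

    Each co-culture well contributes its seeding-corrected log(GFP/SRB);
    each KO mono-culture (calibration) well contributes its raw
    log(GFP/SRB).  Under the null of identical WT/KO growth both equal
    the log calibration slope, and — crucially — the calibration wells'
    own variability sits in the residual, so the test stays calibrated
    even though every expected value shares one fitted slope.  The log
    scale stabilizes the multiplicative plate-reader noise across the
    1000-fold signal growth of a week-long time course.
    """
    p = _degenerate_p(long)
    if p is not None:
        return p
    model = smf.ols("y ~ C(kind) + C(day) + C(kind):C(day)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return float(table.loc["C(kind)", "PR(>F)"])


def _ratio_test_permutation(
    long: pd.DataFrame, n_permutations: int, rng: np.random.Generator
) -> float:
    """Permutation oracle: shuffle well labels (measured vs expected)
    within each day; wells are exchangeable under the null."""
    p = _degenerate_p(long)
    if p is not None:
        return p

    y = long["y"].to_numpy()
    is_meas = (long["kind"] == "measured").to_numpy()
    day_groups = [
        long.index.get_indexer(idx) for _, idx in long.groupby("day").groups.items()
    ]

    def statistic(meas_mask) -> float:
        return abs(y[meas_mask].mean() - y[~meas_mask].mean())

    obs = statistic(is_meas)
    count = 0
    for _ in range(n_permutations):
        perm = is_meas.copy()
        for loc in day_groups:
            perm[loc] = rng.permutation(perm[loc])
        if perm.all() or not perm.any():
            continue
        if statistic(perm) >= obs - 1e-15:
            count += 1
    return (count + 1) / (n_permutations + 1)


def enrichment_test(
    plate: GrowthPlate,
    *,
    calibration: GfpSrbCalibration | None = None,
    alpha: float = 0.05,
    endpoint_day: int | None = None,
    method: str = "anova",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> RescueResult:
    """Test each seeding ratio for GFP enrichment above expectation.

    For every seeding ratio, the measured GFP trajectory is compared
    against the SRB trajectory scaled by the seeding fraction via the
    calibration, as a two-factor analysis (trajectory kind x day) on
    replicate wells; the comparison runs on per-well log GFP/SRB ratios
    so that plate-reader noise is variance-stabilized and the
    calibration wells' own spread enters the residual (see
    :func:`_ratio_test_anova`).  A ratio is flagged significant when
    p < ``alpha`` and the endpoint measured GFP exceeds the expected
    GFP.  With a single replicate only the enrichment ratio is reported
    (p_value None).

    ``method`` selects the parametric two-factor ANOVA (default) or a
    seeded within-day permutation test used as its oracle.
    """
    if calibration is None:
        calibration = calibrate_gfp_srb(plate)
    rng = np.random.default_rng(seed)
    results: list[RatioResult] = []
    for (s_ko, s_wt), grp in plate.wells.groupby(["seeding_ko", "seeding_wt"]):
        total = s_ko + s_wt
        # WT mono-cultures carry no labeled compartment: enrichment undefined
        if total == 0 or s_ko == 0:
            continue
        frac = s_ko / total
        days = np.sort(grp["day"].unique())
        end_day = endpoint_day if endpoint_day is not None else days.max()
        exp_vals = expected_gfp(grp["srb"], frac, calibration)
        ko_mono = plate.wells[plate.wells["condition"] == "ko_mono"]
        ok_co = (grp["gfp"] > 0) & (grp["srb"] > 0)
        ok_cal = (ko_mono["gfp"] > 0) & (ko_mono["srb"] > 0)
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "y": np.log(grp.loc[ok_co, "gfp"] / grp.loc[ok_co, "srb"]).to_numpy()
                        - math.log(frac),
                        "day": grp.loc[ok_co, "day"].to_numpy(),
                        "kind": "measured",
                    }
                ),
                pd.DataFrame(
                    {
                        "y": np.log(
                            ko_mono.loc[ok_cal, "gfp"] / ko_mono.loc[ok_cal, "srb"]
                        ).to_numpy(),
                        "day": ko_mono.loc[ok_cal, "day"].to_numpy(),
                        "kind": "expected",
                    }
                ),
            ],
            ignore_index=True,
        )
        meas_by_day = grp.groupby("day")["gfp"].mean()
        exp_by_day = (
            pd.Series(exp_vals, index=grp["day"].to_numpy()).groupby(level=0).mean()
        )
        meas_end = float(meas_by_day.loc[end_day])
        exp_end = float(exp_by_day.loc[end_day])
        ratio = meas_end / exp_end if exp_end > 0 else math.inf if meas_end > 0 else 1.0

        replicates = grp.groupby("day")["well_id"].nunique().min()
        if replicates < 2:
            p = None
            sig = False
        else:
            if method == "anova":
                p = _ratio_test_anova(long)
            elif method == "permutation":
                p = _ratio_test_permutation(long, n_permutations, rng)
            else:
                raise ValueError(f"unknown method {method!r}")
            sig = bool(p < alpha and meas_end > exp_end)
        results.append(
            RatioResult(
                seeding_ko=int(s_ko),
                seeding_wt=int(s_wt),
                days=meas_by_day.index.to_numpy(),
                measured_gfp=meas_by_day.to_numpy(),
                expected_gfp=exp_by_day.to_numpy(),
                enrichment_ratio=ratio,
                p_value=p,
                significant=sig,
            )
        )
    return RescueResult(per_ratio=results)


class PhRecovery(NamedTuple):
    rate: float  # dpH/dt in pH units/min
    nadir_index: int
    nadir_ph: float
    negative_slope: bool  # warning flag: pH kept falling after the nadir


def phi_recovery_rate(
    times, ph, *, window: float = 5.0, min_points: int = 4
) -> PhRecovery:
    """Acid-extrusion activity as the pH recovery slope after an acid load.

    Finds the trace nadir (minimum pH) and fits a straight line to the
    ``window`` minutes that follow it.  A flat post-nadir trace gives
    slope 0 (transporter-null / inhibitor phenotype); a negative slope
    is returned as-is with ``negative_slope`` set.
    """
    times = np.asarray(times, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if times.shape != ph.shape or times.ndim != 1:
        raise ValueError("times and ph must be 1-D arrays of equal length")
    if np.any((ph < 5.5) | (ph > 8.5)):
        raise ValueError("pH values outside the physiological range (5.5, 8.5)")
    nadir = int(np.argmin(ph))
    sel = (times >= times[nadir]) & (times <= times[nadir] + window)
    if sel.sum() < min_points:
        raise ValueError(
            f"no usable nadir: only {int(sel.sum())} samples within {window} min after minimum"
        )
    slope = float(np.polyfit(times[sel], ph[sel], 1)[0])
    return PhRecovery(
        rate=slope, nadir_index=nadir, nadir_ph=float(ph[nadir]), negative_slope=slope < 0
    )


class ModeOffset(NamedTuple):
    offsets: np.ndarray
    mode: float
    sd: float
    central90_width: float


def distribution_offset_to_mode(values, bin_width: float = 0.05) -> ModeOffset:
    """Center a per-cell pH distribution on its histogram mode.

    Aligning each condition's distribution on its mode isolates the
    cell-to-cell spread from shifts of the set point; the spread is
    reported as the SD and the central-90% width of the offsets.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 30:
        raise ValueError(f"need >= 30 values, got {values.size}")
    if np.ptp(values) == 0:
        return ModeOffset(values - values[0], float(values[0]), 0.0, 0.0)
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    mode = float((edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2)
    offsets = values - mode
    q5, q95 = np.percentile(offsets, [5, 95])
    return ModeOffset(offsets, mode, float(np.std(offsets, ddof=1)), float(q95 - q5))
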