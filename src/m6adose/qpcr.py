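"""qPCR-side quantification: MeRIP enrichment, ddCt expression, SELECT
single-base m6A fractions, and control-referenced group testing.

All amount arithmetic assumes amount proportional to efficiency^(-Ct) with a
configurable amplification efficiency (default 2.0, perfect doubling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "relative_amount",
    "merip_enrichment",
    "merip_enrichment_table",
    "relative_m6a_level",
    "primer_feasibility",
    "relative_expression_ddct",
    "SelectStandardCurve",
    "fit_select_curve",
    "estimate_select_fraction",
    "GroupComparison",
    "anova_dunnett",
]

# MeRIP fraction masses from the assay protocol: 2 ug IP, 500 ng input.
DEFAULT_MASS_IP_NG = 2000.0
DEFAULT_MASS_INPUT_NG = 500.0


def _check_efficiency(efficiency: float) -> None:
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must be in (1, 2]")


def relative_amount(ct, efficiency: float = 2.0):
    """Relative template amount efficiency^(-ct); strictly decreasing in ct."""
    _check_efficiency(efficiency)
    ct = np.asarray(ct, dtype=float)
    out = efficiency ** (-ct)
    return float(out) if out.ndim == 0 else out


def merip_enrichment(
    ct_ip,
    ct_input,
    mass_ip_ng: float = DEFAULT_MASS_IP_NG,
    mass_input_ng: float = DEFAULT_MASS_INPUT_NG,
    efficiency: float = 2.0,
):
    """IP enrichment: amount in IP over amount in input at equal RNA mass.

    enrichment = efficiency^(ct_input - ct_ip) * mass_input_ng / mass_ip_ng.
    Amounts are rescaled to a common RNA mass before the ratio, so scaling
    both masses by a common factor leaves the result unchanged.
    """
    _check_efficiency(efficiency)
    mass_ip_ng = np.asarray(mass_ip_ng, dtype=float)
    mass_input_ng = np.asarray(mass_input_ng, dtype=float)
    if np.any(mass_ip_ng <= 0) or np.any(mass_input_ng <= 0):
        raise ValueError("RNA masses must be positive")
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    out = efficiency ** (ct_input - ct_ip) * (mass_input_ng / mass_ip_ng)
    return float(out) if out.ndim == 0 else out


def merip_enrichment_table(ct_records: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per-replicate enrichment from a tidy Ct table.

    Pairs IP with input records on (target_id, primer_id, group_id,
    replicate); a missing partner raises.  Returns columns target_id,
    primer_id, group_id, replicate, dose_gy, tpi, enrichment.
    """
    keys = ["target_id", "primer_id", "group_id", "replicate"]
    ip = ct_records[ct_records["fraction"] == "IP"]
    inp = ct_records[ct_records["fraction"] == "input"]
    merged = ip.merge(inp, on=keys, suffixes=("_ip", "_input"), how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        orphan = merged.loc[merged["_merge"] != "both", keys].iloc[0].tolist()
        raise ValueError(f"unpaired IP/input record for {orphan}")
    enr = merip_enrichment(
        merged["ct_ip"].to_numpy(),
        merged["ct_input"].to_numpy(),
        mass_ip_ng=merged["rna_mass_ng_ip"].to_numpy(),
        mass_input_ng=merged["rna_mass_ng_input"].to_numpy(),
        efficiency=efficiency,
    )
    out = merged[keys].copy()
    out["dose_gy"] = merged.get("dose_gy_ip")
    out["tpi"] = merged.get("tpi_ip")
    out["enrichment"] = enr
    return out


def relative_m6a_level(group_enrichments, control_enrichments) -> tuple[float, float]:
    """Group mean enrichment normalized to the un-irradiated control group.

    Returns (fold, standard error), the SE propagated by the delta method:
    Var(g/c) ~ (g/c)^2 (Var_g / (n_g g^2) + Var_c / (n_c c^2)).  The control
    group normalized to itself gives fold 1 with SE from both terms.
    """
    g = np.asarray(group_enrichments, dtype=float)
    c = np.asarray(control_enrichments, dtype=float)
    if g.size < 1 or c.size < 1:
        raise ValueError("need at least one value per group")
    mg, mc = g.mean(), c.mean()
    if mc == 0:
        raise ValueError("control mean enrichment is zero")
    fold = mg / mc
    vg = g.var(ddof=1) / g.size if g.size > 1 else 0.0
    vc = c.var(ddof=1) / c.size if c.size > 1 else 0.0
    se = abs(fold) * np.sqrt(vg / mg**2 + vc / mc**2) if mg != 0 else np.nan
    return float(fold), float(se)


def primer_feasibility(
    ip_enrichment: float, igg_enrichment: float, min_signal_ratio: float = 4.0
) -> tuple[bool, float]:
    """Primer passes when the m6A-IP signal clears the IgG background.

    pass iff ip_enrichment / igg_enrichment >= min_signal_ratio (boundary
    inclusive).  Returns (passed, ratio).
    """
    if ip_enrichment <= 0 or igg_enrichment <= 0:
        raise ValueError("enrichments must be positive")
    ratio = ip_enrichment / igg_enrichment
    return bool(ratio >= min_signal_ratio), float(ratio)


def relative_expression_ddct(
    ct_target_sample,
    ct_ref_sample,
    ct_target_control,
    ct_ref_control,
    efficiency: float = 2.0,
):
    """Relative expression by the ddCt method against a reference gene.

    fold = efficiency^(-ddCt), ddCt = (ct_target_s - ct_ref_s) -
    (ct_target_c - ct_ref_c).
    """
    _check_efficiency(efficiency)
    ddct = (np.asarray(ct_target_sample, float) - np.asarray(ct_ref_sample, float)) - (
        np.asarray(ct_target_control, float) - np.asarray(ct_ref_control, float)
    )
    out = efficiency ** (-ddct)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# SELECT standard curve
# ---------------------------------------------------------------------------


class SelectStandardCurve(BaseEstimator):
    """Linear calibration of SELECT relative product against m6A fraction.

    The relative product of a reaction is its 2^Ct value normalized to the
    2^Ct value of the 100% m6A standard: r = 2^(ct - ct_ref_100) in the
    default ``normalization='literal'`` mode.  The alternative
    ``'abundance'`` mode reads the product as template abundance 2^(-Ct),
    giving r = 2^(ct_ref_100 - ct); both yield a linear calibration with
    opposite slope signs.  Fitting is ordinary least squares of r on the
    known fractions; fraction estimation inverts the line and clamps to
    [0, 1].

    Attributes (after fit): ``slope_``, ``intercept_``, ``r2_``,
    ``ct_ref_100_``.
    """

    def __init__(self, normalization: str = "literal"):
        self.normalization = normalization

    def _relative_product(self, ct, ct_ref_100):
        ct = np.asarray(ct, dtype=float)
        if self.normalization == "literal":
            return 2.0 ** (ct - ct_ref_100)
        if self.normalization == "abundance":
            return 2.0 ** (ct_ref_100 - ct)
        raise ValueError(f"unknown normalization {self.normalization!r}")

    def fit(self, fractions, cts):
        f = np.asarray(fractions, dtype=float)
        ct = np.asarray(cts, dtype=float)
        if f.shape != ct.shape or f.ndim != 1:
            raise ValueError("fractions and cts must be 1-d arrays of equal length")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if len(np.unique(f)) < 3:
            raise ValueError("standard series needs >= 3 distinct fractions")
        anchor = np.isclose(f, 1.0)
        if not anchor.any():
            raise ValueError("standard series must include the 100% m6A standard")
        self.ct_ref_100_ = float(ct[anchor].mean())
        r = self._relative_product(ct, self.ct_ref_100_)
        slope, intercept = np.polyfit(f, r, 1)
        if slope == 0:
            raise ValueError("degenerate standard curve: zero slope")
        pred = intercept + slope * f
        ss_res = float(((r - pred) ** 2).sum())
        ss_tot = float(((r - r.mean()) ** 2).sum())
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return self

    def estimate_fraction(self, ct_sample, clamp: bool = True):
        """m6A fraction(s) for sample Ct value(s) via the inverted line.

        Returns (fraction, out_of_range flag) for scalars, or arrays of both
        for vector input.
        """
        if not hasattr(self, "slope_"):
            raise ValueError("curve is not fitted")
        r = self._relative_product(ct_sample, self.ct_ref_100_)
        raw = (r - self.intercept_) / self.slope_
        raw = np.asarray(raw, dtype=float)
        out_of_range = (raw < 0) | (raw > 1)
        frac = np.clip(raw, 0.0, 1.0) if clamp else raw
        if frac.ndim == 0:
            return float(frac), bool(out_of_range)
        return frac, out_of_range

    def to_dict(self) -> dict:
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "r2": self.r2_,
            "ct_ref_100": self.ct_ref_100_,
            "normalization": self.normalization,
        }


def fit_select_curve(fractions, cts, normalization: str = "literal") -> SelectStandardCurve:
    """Fit the SELECT calibration line (thin wrapper over SelectStandardCurve)."""
    return SelectStandardCurve(normalization=normalization).fit(fractions, cts)


def estimate_select_fraction(ct_sample, curve: SelectStandardCurve, clamp: bool = True):
    """Estimate single-base m6A fraction(s) from sample Ct via the fitted curve."""
    return curve.estimate_fraction(ct_sample, clamp=clamp)


# ---------------------------------------------------------------------------
# ANOVA + Dunnett many-to-one comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    group_ids: tuple
    means: np.ndarray
    sds: np.ndarray
    sizes: np.ndarray
    f_statistic: float
    f_pvalue: float
    control_index: int
    t_statistics: np.ndarray  # vs control, pooled variance
    raw_pvalues: np.ndarray
    adjusted_pvalues: np.ndarray
    n_mc: int
    seed: int


def anova_dunnett(
    groups,
    control_index: int = 0,
    n_mc: int = 100_000,
    seed: int = 0,
    group_ids=None,
) -> GroupComparison:
    """One-way ANOVA followed by Dunnett's many-to-one test vs the control.

    The Dunnett adjustment is Monte-Carlo: under the common-variance null
    with the study's group sizes, draw group means N(0, 1/n_i) and a pooled
    variance chi^2_df/df, form the max over comparisons of |t|, and report
    adjusted p_i = P(max|T| >= |t_i|).  Exact for unbalanced designs up to MC
    error; the known inequality adjusted >= raw is enforced by clipping.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 replicates per group")
    if not 0 <= control_index < k:
        raise ValueError("control_index out of range")
    sizes = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    sds = np.array([a.std(ddof=1) for a in arrays])
    N = int(sizes.sum())
    df = N - k
    mse = float(sum(((a - a.mean()) ** 2).sum() for a in arrays) / df)

    f_stat, f_p = stats.f_oneway(*arrays)

    others = [i for i in range(k) if i != control_index]
    n0 = sizes[control_index]
    denom = np.sqrt(mse * (1.0 / sizes[others] + 1.0 / n0))
    t_obs = (means[others] - means[control_index]) / denom
    raw_p = 2.0 * stats.t.sf(np.abs(t_obs), df)

    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(9,)))
    # null draws: group means (unit sigma) and pooled variance estimate
    zm = rng.normal(0.0, 1.0, size=(n_mc, k)) / np.sqrt(sizes)
    s2 = rng.chisquare(df, size=n_mc) / df
    tm = (zm[:, others] - zm[:, [control_index]]) / np.sqrt(
        s2[:, None] * (1.0 / sizes[others] + 1.0 / n0)
    )
    max_abs_t = np.abs(tm).max(axis=1)
    adj = (1.0 + (max_abs_t[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) / (n_mc + 1.0)
    adj = np.minimum(1.0, np.maximum(adj, raw_p))

    t_full = np.full(k, np.nan)
    p_full = np.full(k, np.nan)
    a_full = np.full(k, np.nan)
    t_full[others] = t_obs
    p_full[others] = raw_p
    a_full[others] = adj
    return GroupComparison(
        group_ids=tuple(group_ids) if group_ids is not None else tuple(range(k)),
        means=means,
        sds=sds,
        sizes=sizes,
        f_statistic=float(f_stat),
        f_pvalue=float(f_p),
        control_index=control_index,
        t_statistics=t_full,
        raw_pvalues=p_full,
        adjusted_pvalues=a_full,
        n_mc=n_mc,
        seed=seed,
    )
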