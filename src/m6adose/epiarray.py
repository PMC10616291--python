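"""Two-channel epitranscriptomic array quantification.

The array hybridizes the immunoprecipitated (IP, m6A-containing) and
supernatant (Sup, unmodified) fractions of each sample on two channels.
After centering each channel on its spike-in control probes, the per-gene
m6A modification level is the IP share of the total signal, expressed as a
percentage, and the m6A quantity is the normalized linear IP intensity.
Differential methylation between an exposed and a control group is called by
fold change (> fc_hi or < fc_lo) together with a two-sided t-test on
log2-transformed levels (p < alpha), both inequalities strict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_spikein",
    "compute_m6a_level",
    "compute_m6a_quantity",
    "m6a_level_matrix",
    "differential_m6a",
    "temporal_diff_table",
]

_ARRAY_COLUMNS = ["probe_id", "gene_id", "is_spikein", "sample_id", "ip_intensity", "sup_intensity"]


def _check_array_table(table: pd.DataFrame) -> None:
    missing = [c for c in _ARRAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"array table missing columns: {missing}")
    for col in ("ip_intensity", "sup_intensity"):
        vals = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"{col} must be strictly positive and finite")


def normalize_spikein(table: pd.DataFrame) -> pd.DataFrame:
    """Center each sample's channels on its spike-in probes.

    Per sample and per channel, every log2 intensity is shifted by the
    negative of the mean log2 spike-in intensity of that channel (i.e. linear
    intensities are divided by the geometric mean spike-in intensity).  After
    normalization, the mean log2 spike-in intensity of each channel is 0 and
    the rank order of non-spike-in probes within a channel is unchanged.

    Parameters
    ----------
    table : tidy array table with columns probe_id, gene_id, is_spikein,
        sample_id, ip_intensity, sup_intensity (linear scale, positive).

    Returns
    -------
    A copy of the table with normalized intensities.
    """
    _check_array_table(table)
    spikes = table[table["is_spikein"].astype(bool)]
    if spikes.empty:
        raise ValueError("no spike-in probes: spike-in normalization is impossible")
    out = table.copy()
    for col in ("ip_intensity", "sup_intensity"):
        log_means = np.log2(spikes[col].to_numpy(dtype=float))
        centers = (
            pd.Series(log_means, index=spikes["sample_id"].to_numpy())
            .groupby(level=0)
            .mean()
        )
        if not set(out["sample_id"]) <= set(centers.index):
            raise ValueError("every sample needs at least one spike-in probe")
        shift = out["sample_id"].map(centers).to_numpy(dtype=float)
        out[col] = out[col].to_numpy(dtype=float) / 2.0**shift
    return out


def compute_m6a_level(ip, sup):
    """m6A modification level: the IP percentage of total signal.

    level = 100 * ip / (ip + sup), bounded in (0, 100) for positive inputs.
    Vectorized; raises if any pair is non-positive in both entries or any
    entry is negative.
    """
    ip = np.asarray(ip, dtype=float)
    sup = np.asarray(sup, dtype=float)
    if np.any(ip < 0) or np.any(sup < 0):
        raise ValueError("intensities must be non-negative")
    total = ip + sup
    if np.any(total == 0):
        raise ValueError("m6A level undefined where both channels are zero")
    out = 100.0 * ip / total
    return float(out) if out.ndim == 0 else out


def compute_m6a_quantity(ip_normalized):
    """m6A quantity: the normalized linear IP intensity, kept as a named output."""
    ip = np.asarray(ip_normalized, dtype=float)
    if np.any(ip <= 0):
        raise ValueError("normalized IP intensity must be positive")
    return float(ip) if ip.ndim == 0 else ip.copy()


def m6a_level_matrix(
    table: pd.DataFrame, normalize: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample matrices of m6A level (%) and m6A quantity.

    Spike-in probes are used for normalization (when requested) and excluded
    from the output.  Multiple probes per gene are averaged on the linear
    intensity scale before the level is computed.
    """
    if normalize:
        table = normalize_spikein(table)
    else:
        _check_array_table(table)
    genes = table[~table["is_spikein"].astype(bool)]
    ip = genes.pivot_table(index="gene_id", columns="sample_id", values="ip_intensity", aggfunc="mean")
    sup = genes.pivot_table(index="gene_id", columns="sample_id", values="sup_intensity", aggfunc="mean")
    if ip.isna().any().any() or sup.isna().any().any():
        raise ValueError("probe set must be identical across samples")
    levels = compute_m6a_level(ip.to_numpy(), sup.to_numpy())
    levels = pd.DataFrame(levels, index=ip.index, columns=ip.columns)
    quantity = pd.DataFrame(compute_m6a_quantity(ip.to_numpy()), index=ip.index, columns=ip.columns)
    return levels, quantity


def _log2_ttest(
    exp_log: np.ndarray, ctl_log: np.ndarray, equal_means: np.ndarray, welch: bool
) -> np.ndarray:
    """Row-wise two-sided t-test p-values with defined degenerate behaviour.

    Zero within-group variance in both groups: p = 1 when the means are
    equal, p = 0 (with a warning upstream) when they differ.
    """
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance rows trigger scipy precision warnings; their p-values
        # are overwritten by the explicit degenerate rules below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(exp_log, ctl_log, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def differential_m6a(
    levels_exposed: pd.DataFrame,
    levels_control: pd.DataFrame,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    alpha: float = 0.01,
    welch: bool = False,
) -> pd.DataFrame:
    """Call differential m6A methylation between an exposed and control group.

    Fold change is the ratio of group means on the level (linear percentage)
    scale; the p-value comes from a two-sided unpaired t-test on
    log2-transformed levels (Student by default, Welch with ``welch=True``).
    A gene is ``hyper`` iff fold change > fc_hi and p < alpha, ``hypo`` iff
    fold change < fc_lo and p < alpha, otherwise ``ns`` — all inequalities
    strict.  A Benjamini-Hochberg FDR column is reported for information only;
    the status calls use the raw p-values.

    Parameters
    ----------
    levels_exposed, levels_control : gene x replicate DataFrames of m6A
        levels, indexed by gene_id, with at least 2 replicates each and
        strictly positive values.

    Returns
    -------
    DataFrame with columns gene_id, log2_fc, p_value, bh_fdr, status.
    """
    if not levels_exposed.index.equals(levels_control.index):
        levels_control = levels_control.reindex(levels_exposed.index)
        if levels_control.isna().any().any():
            raise ValueError("exposed and control gene sets differ")
    if levels_exposed.shape[1] < 2 or levels_control.shape[1] < 2:
        raise ValueError("differential testing requires >= 2 replicates per group")
    exp = levels_exposed.to_numpy(dtype=float)
    ctl = levels_control.to_numpy(dtype=float)
    if np.any(exp <= 0) or np.any(ctl <= 0):
        raise ValueError("m6A levels must be strictly positive")

    fc = exp.mean(axis=1) / ctl.mean(axis=1)
    equal_means = np.isclose(exp.mean(axis=1), ctl.mean(axis=1))
    p = _log2_ttest(np.log2(exp), np.log2(ctl), equal_means, welch)
    if np.any((p == 0.0) & ~equal_means & (exp.std(axis=1) == 0) & (ctl.std(axis=1) == 0)):
        warnings.warn(
            "zero within-group variance with unequal means: p set to 0", RuntimeWarning
        )
    status = np.where(
        (fc > fc_hi) & (p < alpha), "hyper", np.where((fc < fc_lo) & (p < alpha), "hypo", "ns")
    )
    bh = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": levels_exposed.index.to_numpy(),
            "log2_fc": np.log2(fc),
            "p_value": p,
            "bh_fdr": bh,
            "status": status,
        }
    )


def temporal_diff_table(
    levels: pd.DataFrame,
    samples: pd.DataFrame,
    exposed_dose: float,
    control_dose: float = 0.0,
    **diff_kwargs,
) -> dict[float, pd.DataFrame]:
    """Differential calls per timepoint: exposed dose vs control dose.

    ``levels`` is the gene x sample level matrix; ``samples`` the annotation
    table (sample_id, dose_gy, tpi_days, replicate).  Returns a mapping
    timepoint -> differential-call table.
    """
    out: dict[float, pd.DataFrame] = {}
    for tpi in sorted(samples["tpi_days"].unique()):
        sel = samples[samples["tpi_days"] == tpi]
        exp_ids = sel.loc[sel["dose_gy"] == exposed_dose, "sample_id"]
        ctl_ids = sel.loc[sel["dose_gy"] == control_dose, "sample_id"]
        if exp_ids.empty or ctl_ids.empty:
            continue
        out[float(tpi)] = differential_m6a(levels[list(exp_ids)], levels[list(ctl_ids)], **diff_kwargs)
    return out
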