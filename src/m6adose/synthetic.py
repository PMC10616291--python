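"""Synthetic study generator for the m6A biodosimetry pipeline.

Every downstream stage (array quantification, two-stage screening, qPCR
arithmetic, dose-model fitting) consumes tables that this module can produce
with known ground truth: a saturating dose-response surface with a unimodal
time course, planted hyper-/hypo-methylated transcripts over a null
transcriptome, spike-in probes around sample-specific scale factors, and Ct
values generated by inverting the quantification formulas.

Reproducibility contract: every ``simulate_*`` function is a pure function of
its arguments and ``seed``.  A single global seed expands into independent
per-component streams via :func:`stream_rng`, so any subset of the simulated
study can be regenerated on its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "ResponseSurfaceParams",
    "PlantedEffect",
    "SimulatedStudy",
    "DEFAULT_DESIGN",
    "NCOA4_LIKE",
    "ATE1_LIKE",
    "FGF22_LIKE",
    "stream_rng",
    "response_surface",
    "simulate_dose_response",
    "simulate_epiarray",
    "simulate_ct_data",
    "simulate_merip_ct",
    "simulate_select_ct",
    "simulate_expression_ct",
    "simulate_polynomial_doses",
    "simulate_study",
]

# Named sub-streams of the global seed.  SeedSequence(seed, spawn_key=(k,))
# gives statistically independent streams for distinct k; the mapping below
# is fixed so that regenerating one component never perturbs another.
STREAMS = {
    "dose_response": 1,
    "epiarray": 2,
    "epiarray_stage2": 3,
    "ct_merip": 4,
    "ct_select": 5,
    "ct_expression": 6,
    "polynomial": 7,
}


def stream_rng(seed: int, stream: int | str) -> np.random.Generator:
    """Return the RNG for one named (or numbered) sub-stream of ``seed``."""
    key = STREAMS[stream] if isinstance(stream, str) else int(stream)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Dose x time x replicate layout of an irradiation study.

    Defaults mirror the mouse total-body-irradiation design: gamma-ray doses
    0.2-6.5 Gy plus a sham (0 Gy) arm, sampling on days 1, 3, 7, 14 and 28,
    five animals per group.  ``extra_groups`` admits arms outside the full
    grid, e.g. a 10 Gy arm restricted to days 1 and 3.
    """

    doses: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0, 4.0, 6.5)
    timepoints: tuple[float, ...] = (1.0, 3.0, 7.0, 14.0, 28.0)
    replicates_per_group: int = 5
    include_sham: bool = True
    extra_groups: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        tps = tuple(float(t) for t in self.timepoints)
        if len(doses) == 0 or len(tps) == 0:
            raise ValueError("design must contain at least one dose and one timepoint")
        if any(d < 0 for d in doses):
            raise ValueError("doses must be non-negative")
        if list(doses) != sorted(set(doses)):
            raise ValueError("doses must be distinct and sorted ascending")
        if any(t <= 0 for t in tps):
            raise ValueError("timepoints must be positive")
        if list(tps) != sorted(set(tps)):
            raise ValueError("timepoints must be distinct and sorted ascending")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be >= 1")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "timepoints", tps)

    @property
    def all_doses(self) -> tuple[float, ...]:
        if self.include_sham and 0.0 not in self.doses:
            return (0.0,) + self.doses
        return self.doses

    def groups(self) -> list[tuple[float, float]]:
        """All (dose_gy, tpi_days) groups, grid plus extra arms."""
        grid = [(d, t) for d in self.all_doses for t in self.timepoints]
        return grid + [(float(d), float(t)) for d, t in self.extra_groups]

    @classmethod
    def default(cls, include_10gy_arm: bool = False, **kwargs) -> "StudyDesign":
        extra = (((10.0, 1.0), (10.0, 3.0)) if include_10gy_arm else ())
        return cls(extra_groups=extra, **kwargs)


DEFAULT_DESIGN = StudyDesign()


# ---------------------------------------------------------------------------
# Dose-time response surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseSurfaceParams:
    """Parametric dose-time surface for a relative m6A level (fold over sham).

    surface(d, t) = baseline + A * d^h / (d^h + K^h) * exp(-ln(t/t_peak)^2 / (2 w^2))

    ``amplitude`` (A) is the maximal fold elevation over baseline, ``half_dose``
    (K, Gy) the dose of half-maximal response, ``hill`` (h) the steepness,
    ``peak_time`` (t_peak, days) the mode of the log-normal time kernel and
    ``time_width`` (w, log-days) its width.  The surface equals ``baseline``
    at dose 0 for every t and is non-decreasing in dose.
    """

    amplitude: float = 3.0
    half_dose: float = 3.0
    hill: float = 1.5
    peak_time: float = 14.0
    time_width: float = 1.5
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        for name in ("half_dose", "hill", "peak_time", "time_width", "baseline"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Persistent marker: peaks at day 14 and stays detectable through day 28.
NCOA4_LIKE = ResponseSurfaceParams()
#: Early marker: peaks at day 1 and decays within about a week.
ATE1_LIKE = ResponseSurfaceParams(amplitude=3.0, peak_time=1.0, time_width=1.0)
#: Early, weaker marker with the fastest recovery.
FGF22_LIKE = ResponseSurfaceParams(amplitude=2.0, peak_time=1.0, time_width=0.8)


def response_surface(dose, tpi, params: ResponseSurfaceParams):
    """Expected relative m6A level (fold over sham) at (dose, tpi).

    Vectorized over ``dose`` and ``tpi``.  Raises for negative dose or
    non-positive time.
    """
    d = np.asarray(dose, dtype=float)
    t = np.asarray(tpi, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    if np.any(t <= 0):
        raise ValueError("tpi must be positive")
    dh = np.power(d, params.hill)
    hill = dh / (dh + params.half_dose**params.hill)
    kernel = np.exp(-(np.log(t / params.peak_time) ** 2) / (2.0 * params.time_width**2))
    out = params.baseline + params.amplitude * hill * kernel
    return float(out) if out.ndim == 0 else out


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean exactly 1 and the given CV."""
    if cv < 0:
        raise ValueError("noise coefficient of variation must be non-negative")
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_dose_response(
    design: StudyDesign,
    params: ResponseSurfaceParams = NCOA4_LIKE,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """One observation per (dose, timepoint, replicate) from the surface.

    Observed value = surface mean x log-normal factor with mean 1 and
    coefficient of variation ``noise_cv``.  Returns a tidy table with columns
    subject_id, m6a_value, m6a_scale, tpi_days, dose_gy.
    """
    if not isinstance(design, StudyDesign):
        raise TypeError("design must be a StudyDesign")
    groups = design.groups()
    if not groups:
        raise ValueError("empty study design")
    rng = stream_rng(seed, "dose_response")
    n = design.replicates_per_group
    rows = []
    for dose, tpi in groups:
        mean = response_surface(dose, tpi, params)
        vals = mean * _lognormal_factor(rng, noise_cv, n)
        for r, v in enumerate(vals, start=1):
            rows.append((f"d{dose:g}_t{tpi:g}_r{r}", float(v), "relative", tpi, dose))
    return pd.DataFrame(
        rows, columns=["subject_id", "m6a_value", "m6a_scale", "tpi_days", "dose_gy"]
    )


# ---------------------------------------------------------------------------
# Two-channel epitranscriptomic array
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth m6A perturbation for one transcript.

    ``pattern`` is one of ``consistent-hyper`` (elevated at every timepoint in
    exposed samples), ``transient-hyper`` (elevated only at ``timepoint``) or
    ``hypo`` (symmetric decrease at every timepoint).  ``effect`` is the fold
    change of the modified fraction (equivalently of the level percentage):
    hyper multiplies the baseline fraction by ``effect``, hypo divides by it.
    """

    pattern: str
    effect: float
    timepoint: float | None = None

    def __post_init__(self) -> None:
        if self.pattern not in ("consistent-hyper", "transient-hyper", "hypo"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.pattern == "transient-hyper" and self.timepoint is None:
            raise ValueError("transient-hyper requires a designated timepoint")


def simulate_epiarray(
    design: StudyDesign,
    n_genes: int = 1000,
    n_spikeins: int = 10,
    planted: Mapping[str, PlantedEffect] | None = None,
    noise_sd_log2: float = 0.15,
    seed: int = 0,
    stream: str = "epiarray",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate two-channel (IP/Sup) probe intensities with planted truth.

    Each gene g carries a fixed baseline modified fraction f_g ~ U(0.05, 0.2)
    and abundance T_g; sample j carries a scale factor s_j (log2-normal,
    sd 0.5) shared by both channels so spike-in normalization is exercised.
    Linear intensities are IP = T f s 2^eps and Sup = T (1-f) s 2^eps' with
    eps ~ N(0, noise_sd_log2) independent per probe/channel/sample; spike-in
    probes sit on a fixed abundance ladder around s_j.  Exposed samples
    (dose > 0) of planted genes have f multiplied (hyper) or divided (hypo)
    by the planted effect, per pattern.

    Returns ``(array_table, sample_table, truth_table)``:
    the tidy probe table (probe_id, gene_id, is_spikein, sample_id,
    ip_intensity, sup_intensity), the sample annotations (sample_id, dose_gy,
    tpi_days, replicate) and per-gene truth labels (gene_id, pattern, effect,
    baseline_fraction).
    """
    if n_spikeins < 3:
        raise ValueError("need at least 3 spike-in probes")
    if noise_sd_log2 < 0:
        raise ValueError("noise_sd_log2 must be non-negative")
    planted = dict(planted or {})
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    gene_set = set(gene_ids)
    unknown = set(planted) - gene_set
    if unknown:
        raise ValueError(f"planted gene ids not in simulated genes: {sorted(unknown)[:5]}")

    rng = stream_rng(seed, stream)
    f0 = rng.uniform(0.05, 0.2, size=n_genes)
    abundance = 2.0 ** rng.normal(10.0, 1.0, size=n_genes)
    spike_abundance = 2.0 ** np.linspace(8.0, 12.0, n_spikeins)

    # validate planted effects against (0, 1) fraction bounds up front
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g, eff in planted.items():
        f = f0[idx[g]]
        fa = f * eff.effect if eff.pattern != "hypo" else f / eff.effect
        if not (0.0 < fa < 1.0):
            raise ValueError(
                f"planted effect for {g} drives modified fraction to {fa:.3g}, outside (0, 1)"
            )

    groups = design.groups()
    nrep = design.replicates_per_group
    samples = []
    for dose, tpi in groups:
        for r in range(1, nrep + 1):
            samples.append((f"s_d{dose:g}_t{tpi:g}_r{r}", dose, tpi, r))
    sample_table = pd.DataFrame(samples, columns=["sample_id", "dose_gy", "tpi_days", "replicate"])

    n_samples = len(samples)
    # fraction matrix genes x samples
    frac = np.tile(f0[:, None], (1, n_samples))
    doses = sample_table["dose_gy"].to_numpy()
    tps = sample_table["tpi_days"].to_numpy()
    for g, eff in planted.items():
        i = idx[g]
        exposed = doses > 0
        if eff.pattern == "consistent-hyper":
            frac[i, exposed] = f0[i] * eff.effect
        elif eff.pattern == "transient-hyper":
            at_tp = exposed & np.isclose(tps, eff.timepoint)
            frac[i, at_tp] = f0[i] * eff.effect
        else:  # hypo
            frac[i, exposed] = f0[i] / eff.effect

    scale = 2.0 ** rng.normal(0.0, 0.5, size=n_samples)

    def noisy(base: np.ndarray) -> np.ndarray:
        if noise_sd_log2 == 0:
            return base
        return base * 2.0 ** rng.normal(0.0, noise_sd_log2, size=base.shape)

    ip = noisy(abundance[:, None] * frac * scale[None, :])
    sup = noisy(abundance[:, None] * (1.0 - frac) * scale[None, :])
    spike = spike_abundance[:, None] * scale[None, :]
    spike_ip = noisy(spike)
    spike_sup = noisy(spike)

    spike_ids = [f"spike{k:02d}" for k in range(n_spikeins)]
    n_probes = n_genes + n_spikeins
    probe_ids = np.concatenate([gene_ids, spike_ids])
    array_table = pd.DataFrame(
        {
            "probe_id": np.tile(probe_ids, n_samples),
            "gene_id": np.tile(probe_ids, n_samples),
            "is_spikein": np.tile(
                np.concatenate([np.zeros(n_genes, bool), np.ones(n_spikeins, bool)]), n_samples
            ),
            "sample_id": np.repeat(sample_table["sample_id"].to_numpy(), n_probes),
            "ip_intensity": np.concatenate([ip, spike_ip]).T.ravel(),
            "sup_intensity": np.concatenate([sup, spike_sup]).T.ravel(),
        }
    )

    truth = pd.DataFrame({"gene_id": gene_ids, "pattern": "null", "effect": 1.0, "baseline_fraction": f0})
    truth = truth.set_index("gene_id")
    for g, eff in planted.items():
        truth.loc[g, ["pattern", "effect"]] = [eff.pattern, eff.effect]
    return array_table, sample_table, truth.reset_index()


# ---------------------------------------------------------------------------
# qPCR Ct generators (inverse of the qpcr_quant formulas)
# ---------------------------------------------------------------------------

_CT_COLUMNS = [
    "target_id",
    "primer_id",
    "fraction",
    "ct",
    "rna_mass_ng",
    "group_id",
    "replicate",
    "dose_gy",
    "tpi",
    "tpi_unit",
]


def _check_ct_sd(ct_sd: float) -> None:
    if ct_sd < 0:
        raise ValueError("ct_sd must be non-negative")


def simulate_merip_ct(
    enrichment_by_group: Mapping[str, float],
    n_replicates: int = 5,
    ct_input_baseline: float = 25.0,
    ct_sd: float = 0.0,
    mass_ip_ng: float = 2000.0,
    mass_input_ng: float = 500.0,
    efficiency: float = 2.0,
    target_id: str = "Ncoa4",
    primer_id: str = "primer1",
    igg_enrichment: float = 0.05,
    include_igg: bool = False,
    group_meta: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate paired IP/input (optionally IgG) Ct records per group.

    Ct values are built by inverting the MeRIP enrichment formula
    (amount proportional to efficiency^-Ct, rescaled to equal RNA mass), so at
    ``ct_sd = 0`` the quantification recovers the planted enrichments exactly.
    ``group_meta`` optionally maps group_id -> (dose_gy, tpi_days).
    """
    _check_ct_sd(ct_sd)
    if any(e <= 0 for e in enrichment_by_group.values()):
        raise ValueError("enrichments must be positive")
    rng = stream_rng(seed, "ct_merip")
    log_eff = np.log(efficiency)
    rows = []
    for group, enr in enrichment_by_group.items():
        dose, tpi = (group_meta or {}).get(group, (np.nan, np.nan))
        for r in range(1, n_replicates + 1):
            ct_in = ct_input_baseline + rng.normal(0, ct_sd) if ct_sd else ct_input_baseline
            # enrichment = eff^(ct_in - ct_ip) * mass_input / mass_ip
            ct_ip = ct_in - np.log(enr * mass_ip_ng / mass_input_ng) / log_eff
            if ct_sd:
                ct_ip += rng.normal(0, ct_sd)
            rows.append((target_id, primer_id, "input", ct_in, mass_input_ng, group, r, dose, tpi, "days"))
            rows.append((target_id, primer_id, "IP", ct_ip, mass_ip_ng, group, r, dose, tpi, "days"))
            if include_igg:
                ct_igg = ct_in - np.log(igg_enrichment * mass_ip_ng / mass_input_ng) / log_eff
                if ct_sd:
                    ct_igg += rng.normal(0, ct_sd)
                rows.append((target_id, primer_id, "IgG", ct_igg, mass_ip_ng, group, r, dose, tpi, "days"))
    return pd.DataFrame(rows, columns=_CT_COLUMNS)


def simulate_select_ct(
    sample_fractions: Mapping[str, float],
    standard_fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    slope: float = 0.9,
    intercept: float = 0.1,
    ct_ref_100: float = 20.0,
    ct_sd: float = 0.0,
    n_replicates: int = 3,
    target_id: str = "Ncoa4_A459",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct records for a SELECT standard series plus unknown samples.

    The true calibration line is r = intercept + slope * fraction on the
    relative-product scale r = 2^(Ct - Ct_100); m6A at the interrogated base
    suppresses elongation, so higher fraction means higher Ct.  Requires
    r > 0 over [0, 1] and 1.0 among the standards (the normalization anchor).

    Returns ``(standards, samples)`` Ct tables.
    """
    _check_ct_sd(ct_sd)
    fracs = [float(f) for f in standard_fractions]
    if not any(np.isclose(f, 1.0) for f in fracs):
        raise ValueError("standard series must include the 100% m6A standard")
    if any(not 0 <= f <= 1 for f in list(sample_fractions.values()) + fracs):
        raise ValueError("m6A fractions must lie in [0, 1]")
    if intercept <= 0 or intercept + slope <= 0:
        raise ValueError("calibration line must keep the relative product positive on [0, 1]")
    rng = stream_rng(seed, "ct_select")

    def ct_of(frac: float) -> float:
        r = intercept + slope * frac
        return ct_ref_100 + np.log2(r)

    std_rows = []
    for f in fracs:
        for r in range(1, n_replicates + 1):
            ct = ct_of(f) + (rng.normal(0, ct_sd) if ct_sd else 0.0)
            std_rows.append((target_id, f"std_{f:g}", "SELECT", ct, 10.0, f"standard_{f:g}", r, np.nan, np.nan, "days"))
    sample_rows = []
    for name, f in sample_fractions.items():
        for r in range(1, n_replicates + 1):
            ct = ct_of(f) + (rng.normal(0, ct_sd) if ct_sd else 0.0)
            sample_rows.append((target_id, "sample", "SELECT", ct, 10.0, name, r, np.nan, np.nan, "days"))
    std = pd.DataFrame(std_rows, columns=_CT_COLUMNS)
    std["m6a_fraction"] = np.repeat(fracs, n_replicates)
    return std, pd.DataFrame(sample_rows, columns=_CT_COLUMNS)


def simulate_expression_ct(
    fold_by_group: Mapping[str, float],
    control_group: str,
    n_replicates: int = 5,
    ct_target_baseline: float = 24.0,
    ct_ref_baseline: float = 18.0,
    ct_sd: float = 0.0,
    target_id: str = "Ncoa4",
    reference_id: str = "Gapdh",
    seed: int = 0,
) -> pd.DataFrame:
    """Target + reference-gene Ct records planting ddCt expression folds.

    ``fold_by_group[control_group]`` must be 1 (the self-normalization
    anchor); other groups' folds are planted via the target Ct shift
    -log2(fold) so relative_expression_ddct recovers them exactly at
    ``ct_sd = 0``.
    """
    _check_ct_sd(ct_sd)
    if control_group not in fold_by_group:
        raise ValueError("control group missing from fold_by_group")
    if any(f <= 0 for f in fold_by_group.values()):
        raise ValueError("expression folds must be positive")
    rng = stream_rng(seed, "ct_expression")
    rows = []
    for group, fold in fold_by_group.items():
        for r in range(1, n_replicates + 1):
            ct_ref = ct_ref_baseline + (rng.normal(0, ct_sd) if ct_sd else 0.0)
            ct_t = ct_target_baseline - np.log2(fold) + (rng.normal(0, ct_sd) if ct_sd else 0.0)
            rows.append((target_id, "expr", "expression", ct_t, 500.0, group, r, np.nan, np.nan, "days"))
            rows.append((reference_id, "expr", "reference", ct_ref, 500.0, group, r, np.nan, np.nan, "days"))
    return pd.DataFrame(rows, columns=_CT_COLUMNS)


def simulate_ct_data(kind: str, true_values: Mapping, ct_baseline: float = 25.0,
                     ct_sd: float = 0.0, seed: int = 0, **kwargs):
    """Dispatch to the MeRIP / SELECT / expression Ct generators.

    ``true_values`` holds per-group enrichments (merip), per-sample m6A
    fractions (select) or per-group expression folds (expression).
    """
    if kind == "merip":
        return simulate_merip_ct(true_values, ct_input_baseline=ct_baseline, ct_sd=ct_sd, seed=seed, **kwargs)
    if kind == "select":
        return simulate_select_ct(true_values, ct_sd=ct_sd, seed=seed, **kwargs)
    if kind == "expression":
        return simulate_expression_ct(true_values, ct_target_baseline=ct_baseline, ct_sd=ct_sd, seed=seed, **kwargs)
    raise ValueError(f"unknown Ct simulation kind {kind!r}")


# ---------------------------------------------------------------------------
# Polynomial dose surfaces (for calibration-model parameter recovery)
# ---------------------------------------------------------------------------


def simulate_polynomial_doses(
    coefficients: Sequence[float],
    m6a_values: Sequence[float],
    tpi_values: Sequence[float] | None = None,
    n_per_cell: int = 5,
    noise_cv: float = 0.1,
    seed: int = 0,
    basis: str = "total",
) -> pd.DataFrame:
    """Dose observations from a known polynomial in (m6A [, TPI]).

    For 3 coefficients, dose = b0 + b1 m + b2 m^2 on the ``m6a_values`` grid;
    for a bivariate coefficient vector, dose is the corresponding polynomial
    surface over the (m, t) grid.  Noise is multiplicative log-normal with
    mean 1 applied to the dose response, so least-squares recovery of the
    coefficients is unbiased.
    """
    from .dosimetry import _design_matrix_bivariate, _EXPONENTS_TOTAL

    coeffs = np.asarray(coefficients, dtype=float)
    rng = stream_rng(seed, "polynomial")
    m = np.asarray(m6a_values, dtype=float)
    if tpi_values is None:
        if coeffs.size != 3:
            raise ValueError("univariate simulation needs exactly 3 coefficients")
        mm = np.repeat(m, n_per_cell)
        dose = coeffs[0] + coeffs[1] * mm + coeffs[2] * mm**2
        tt = np.full_like(mm, np.nan)
    else:
        t = np.asarray(tpi_values, dtype=float)
        grid_m, grid_t = np.meshgrid(m, t, indexing="ij")
        mm = np.repeat(grid_m.ravel(), n_per_cell)
        tt = np.repeat(grid_t.ravel(), n_per_cell)
        X = _design_matrix_bivariate(mm, tt, basis=basis)
        if coeffs.size != X.shape[1]:
            raise ValueError(f"expected {X.shape[1]} coefficients for basis={basis!r}")
        dose = X @ coeffs
    dose = dose * _lognormal_factor(rng, noise_cv, dose.shape)
    out = pd.DataFrame(
        {
            "subject_id": [f"p{i}" for i in range(len(mm))],
            "m6a_value": mm,
            "m6a_scale": "percent",
            "tpi_days": tt,
            "dose_gy": dose,
        }
    )
    return out


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """A coherent simulated study: arrays, Ct records, dose-response, truth."""

    design: StudyDesign
    dose_response_points: pd.DataFrame
    array_table: pd.DataFrame
    sample_table: pd.DataFrame
    ct_records: pd.DataFrame
    planted_truth: pd.DataFrame
    seed: int = 0
    stage2_array_table: pd.DataFrame | None = None
    stage2_sample_table: pd.DataFrame | None = None


def simulate_study(
    seed: int = 0,
    n_genes: int = 2000,
    n_planted_consistent: int = 20,
    n_planted_transient: int = 10,
    n_planted_hypo: int = 10,
    effect: float = 4.0,
    noise_sd_log2: float = 0.15,
    noise_cv: float = 0.1,
    params: ResponseSurfaceParams = NCOA4_LIKE,
    design: StudyDesign = DEFAULT_DESIGN,
) -> SimulatedStudy:
    """Simulate the full two-stage screening + dosimetry study.

    Stage I arrays compare the highest dose against sham across all
    timepoints; stage II arrays use a 2 Gy arm at days 1 and 14 (or the two
    extreme timepoints of a custom design).  Planted consistent-hyper genes
    are the intended candidates; transient-hyper and hypo genes exercise the
    categorization and sub-clustering stages.  The dose-response table comes
    from the response surface over the full design.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(0,)))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    n_plant = n_planted_consistent + n_planted_transient + n_planted_hypo
    if n_plant > n_genes:
        raise ValueError("more planted genes than simulated genes")
    chosen = rng.choice(n_genes, size=n_plant, replace=False)
    tp_transient = design.timepoints[1] if len(design.timepoints) > 1 else design.timepoints[0]
    planted: dict[str, PlantedEffect] = {}
    for j, gi in enumerate(chosen):
        if j < n_planted_consistent:
            planted[gene_ids[gi]] = PlantedEffect("consistent-hyper", effect)
        elif j < n_planted_consistent + n_planted_transient:
            planted[gene_ids[gi]] = PlantedEffect("transient-hyper", effect, timepoint=tp_transient)
        else:
            planted[gene_ids[gi]] = PlantedEffect("hypo", effect)

    top_dose = design.doses[-1]
    stage1_design = StudyDesign(
        doses=(top_dose,),
        timepoints=design.timepoints,
        replicates_per_group=design.replicates_per_group,
    )
    stage2_dose = 2.0 if 2.0 in design.doses else design.doses[len(design.doses) // 2]
    stage2_tps = (design.timepoints[0], design.timepoints[-2]) if len(design.timepoints) > 1 else design.timepoints
    stage2_design = StudyDesign(
        doses=(stage2_dose,),
        timepoints=stage2_tps,
        replicates_per_group=design.replicates_per_group,
    )
    arr1, samp1, truth = simulate_epiarray(
        stage1_design, n_genes=n_genes, planted=planted,
        noise_sd_log2=noise_sd_log2, seed=seed, stream="epiarray",
    )
    arr2, samp2, _ = simulate_epiarray(
        stage2_design, n_genes=n_genes, planted=planted,
        noise_sd_log2=noise_sd_log2, seed=seed, stream="epiarray_stage2",
    )
    dr = simulate_dose_response(design, params=params, noise_cv=noise_cv, seed=seed)
    enr = {
        f"d{d:g}": float(response_surface(d, params.peak_time, params)) * 3.0
        for d in design.all_doses
    }
    meta = {f"d{d:g}": (d, params.peak_time) for d in design.all_doses}
    ct = simulate_merip_ct(
        enr, n_replicates=design.replicates_per_group, ct_sd=0.1,
        group_meta=meta, seed=seed,
    )
    return SimulatedStudy(
        design=design,
        dose_response_points=dr,
        array_table=arr1,
        sample_table=samp1,
        ct_records=ct,
        planted_truth=truth,
        seed=seed,
        stage2_array_table=arr2,
        stage2_sample_table=samp2,
    )
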