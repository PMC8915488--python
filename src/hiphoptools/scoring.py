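"""Raw tag-intensity → fitness-defect (FD) scoring for both screening pipelines.

Two laboratories scored the same kind of pooled-deletion fitness experiment
with mirror-image conventions:

* HIPLAB-style: per strain pick the *best tag* (lowest robust CV across
  control arrays), normalize arrays by a median-polish variant with batch
  correction, then ``log2(median control signal / treatment signal)`` —
  a sensitive strain scores **high** (``sensitivity_positive``).
* NIBR-style: average the passing tags, quantile-normalize within each
  study, then ``log2(mean treatment / mean control)`` — a sensitive strain
  scores **low** (``sensitivity_negative``).

Both log-ratio matrices are standardized per screen by the robust z
(subtract screen median, divide by screen MAD) to give the FD / MADL score.
The NIBR branch additionally shrinks scores of strains whose replicates
disagree (a_MADL) and standardizes each strain across screens by the spread
of its central 70% of scores (gene-wise z, significance at z < −5); the
HIPLAB branch calls significance at one-tailed standard-normal P ≤ 0.001,
i.e. FD ≥ 3.0902.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnalysisConfig, ScreenMatrix, TagIntensityTable

logger = logging.getLogger(__name__)

MAD_NORMAL_CONSISTENCY = 1.4826022185056018


def _mad(x: np.ndarray, scaled: bool = False) -> float:
    """Median absolute deviation; unscaled by default (no 1.4826 factor)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return math.nan
    m = float(np.median(np.abs(x - np.median(x))))
    return m * MAD_NORMAL_CONSISTENCY if scaled else m


def fd_significance_threshold(alpha: float) -> float:
    """FD cutoff for one-tailed standard-normal significance: Φ⁻¹(1−alpha)."""
    return float(stats.norm.ppf(1.0 - alpha))


@dataclass
class QCReport:
    """Machine-readable record of every QC decision made during scoring."""

    best_tags: dict[str, str] = field(default_factory=dict)
    background_failures: list[dict] = field(default_factory=list)
    unusable_strains: list[str] = field(default_factory=list)
    degenerate_screens: list[str] = field(default_factory=list)
    invariant_strains: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_tags": self.best_tags,
            "background_failures": self.background_failures,
            "unusable_strains": self.unusable_strains,
            "degenerate_screens": self.degenerate_screens,
            "invariant_strains": self.invariant_strains,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# array-level normalization

def median_polish_normalize(table: TagIntensityTable, *, tol: float = 1e-6,
                            max_iter: int = 20) -> TagIntensityTable:
    """Remove array and batch effects from log2 signals by iterative median sweeps.

    Models ``log2(signal) = overall + array_effect + batch_effect + residual``
    and returns signals with the array and batch effects subtracted (on the
    original intensity scale).  Effects are estimated from the used (strain
    tag) features and the correction applied to every feature on the array.
    Iteration stops when the largest effect update falls below *tol* or
    after *max_iter* sweeps.
    """
    df = table.records.copy()
    arrays = table.arrays
    if len(arrays) < 2:
        logger.warning("median polish: single array, returned unchanged")
        return table.copy()

    used = df[df["used"]]
    wide = used.pivot_table(index=["strain_id", "tag"], columns="array_id",
                            values="signal", aggfunc="first")
    log2w = np.log2(wide)
    array_ids = list(log2w.columns)
    batch_of = dict(zip(arrays["array_id"], arrays["batch"]))
    batches = sorted({batch_of[a] for a in array_ids})

    overall = float(np.nanmedian(log2w.to_numpy()))
    a_eff = pd.Series(0.0, index=array_ids)
    b_eff = pd.Series(0.0, index=batches)

    vals = log2w.to_numpy()
    for _ in range(max_iter):
        max_delta = 0.0
        resid = vals - overall - a_eff.to_numpy() \
            - np.array([b_eff[batch_of[a]] for a in array_ids])
        # array sweep
        delta_a = np.nanmedian(resid, axis=0)
        delta_a = np.where(np.isnan(delta_a), 0.0, delta_a)
        a_eff += delta_a
        max_delta = max(max_delta, float(np.max(np.abs(delta_a))))
        # re-centre array effects into batch effects
        for b in batches:
            members = [a for a in array_ids if batch_of[a] == b]
            shift = float(np.median(a_eff[members]))
            b_eff[b] += shift
            a_eff[members] -= shift
            max_delta = max(max_delta, abs(shift))
        # keep the overall term the grand centre
        shift = float(np.median(b_eff))
        overall += shift
        b_eff -= shift
        if max_delta < tol:
            break

    correction = {a: a_eff[a] + b_eff[batch_of[a]] for a in array_ids}
    corr = df["array_id"].map(correction).fillna(0.0)
    df["signal"] = df["signal"] / np.power(2.0, corr)
    return TagIntensityTable(df)


def normalize_by_study(table: TagIntensityTable) -> TagIntensityTable:
    """Quantile-normalize arrays within each study to the study's mean distribution.

    Operates on log2 signals of used features; no adjustment across studies.
    A study with a single array is returned unchanged.
    """
    df = table.records.copy()
    arrays = table.arrays
    study_of = dict(zip(arrays["array_id"], arrays["study_id"]))

    used_mask = df["used"]
    wide = df[used_mask].pivot_table(index=["strain_id", "tag"],
                                     columns="array_id", values="signal",
                                     aggfunc="first")
    log2w = np.log2(wide)
    out = log2w.copy()
    for study in sorted(set(study_of.values())):
        cols = [a for a in log2w.columns if study_of[a] == study]
        if len(cols) < 2:
            continue
        sub = log2w[cols].to_numpy()
        order = np.argsort(sub, axis=0)
        sorted_vals = np.take_along_axis(sub, order, axis=0)
        mean_dist = np.nanmean(sorted_vals, axis=1)
        normed = np.empty_like(sub)
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(sub.shape[0])[:, None], axis=0)
        for j in range(sub.shape[1]):
            normed[:, j] = mean_dist[ranks[:, j]]
        out[cols] = normed

    long = out.stack().rename("log2n").reset_index()
    key = ["strain_id", "tag", "array_id"]
    df = df.merge(long, on=key, how="left")
    has = df["log2n"].notna()
    df.loc[has, "signal"] = np.power(2.0, df.loc[has, "log2n"])
    df = df.drop(columns="log2n")
    return TagIntensityTable(df)


# ---------------------------------------------------------------------------
# tag QC

def background_filter(table: TagIntensityTable, *, n_mads: float = 5.0,
                      report: QCReport | None = None) -> pd.DataFrame:
    """Flag tags whose signal is indistinguishable from array background.

    Per array the threshold is ``median + n_mads * MAD`` of the raw signals of
    the unused (background) features on that array.  A tag passes the filter
    iff its signal exceeds the threshold on every control array.

    Returns a DataFrame ``(strain_id, tag, passes_background)``.
    """
    df = table.records
    controls = set(table.control_arrays())
    unused = df[~df["used"]]
    thresholds: dict[str, float] = {}
    for array_id, grp in unused.groupby("array_id"):
        sig = grp["signal"].to_numpy()
        thresholds[array_id] = float(np.median(sig)) + n_mads * _mad(sig)

    used = df[df["used"] & df["array_id"].isin(controls)]
    if not thresholds:
        msg = "background filter: no unused features, all tags pass"
        logger.warning(msg)
        if report is not None:
            report.warnings.append(msg)
        out = used[["strain_id", "tag"]].drop_duplicates().copy()
        out["passes_background"] = True
        return out.reset_index(drop=True)

    thr = used["array_id"].map(thresholds)
    ok = used["signal"] > thr.fillna(-np.inf)
    passes = ok.groupby([used["strain_id"], used["tag"]]).all()
    out = passes.rename("passes_background").reset_index()
    if report is not None:
        for _, row in out[~out["passes_background"]].iterrows():
            report.background_failures.append(
                {"strain_id": row["strain_id"], "tag": row["tag"]})
    return out


def select_best_tag(table: TagIntensityTable, *,
                    quality: pd.DataFrame | None = None,
                    report: QCReport | None = None) -> pd.DataFrame:
    """Choose each strain's best tag: lowest robust CV across control arrays.

    robust CV = MAD / median of the tag's raw control-array signals.  Only
    tags passing the background filter compete; ties go to the uptag.
    Strains with no passing tag are flagged unusable and excluded.

    Returns a DataFrame ``(strain_id, tag, robust_cv)``, one row per usable strain.
    """
    if quality is None:
        quality = background_filter(table, report=report)
    df = table.records
    controls = set(table.control_arrays())
    used = df[df["used"] & df["array_id"].isin(controls)]

    rows = []
    passing = quality.set_index(["strain_id", "tag"])["passes_background"]
    for (strain, tag), grp in used.groupby(["strain_id", "tag"], sort=True):
        if not bool(passing.get((strain, tag), False)):
            continue
        sig = grp["signal"].to_numpy()
        med = float(np.median(sig))
        rcv = _mad(sig) / med if med > 0 else math.inf
        rows.append((strain, tag, rcv))
    if not rows:
        return pd.DataFrame(columns=["strain_id", "tag", "robust_cv"])
    cand = pd.DataFrame(rows, columns=["strain_id", "tag", "robust_cv"])
    # tie-break toward the uptag: stable sort on (robust_cv, tag=="down")
    cand = cand.sort_values(["strain_id", "robust_cv", "tag"],
                            ascending=[True, True, False],
                            kind="stable")  # "up" > "down" lexically
    best = cand.groupby("strain_id", sort=True).first().reset_index()

    all_strains = df.loc[df["used"], "strain_id"].unique()
    unusable = sorted(set(all_strains) - set(best["strain_id"]))
    if unusable:
        logger.info("select_best_tag: %d strains with no passing tag", len(unusable))
    if report is not None:
        report.best_tags.update(dict(zip(best["strain_id"], best["tag"])))
        report.unusable_strains.extend(unusable)
    return best


def average_tags(table: TagIntensityTable, *,
                 quality: pd.DataFrame | None = None) -> pd.DataFrame:
    """Average each strain's passing tags per array (NIBR-style strain signal).

    Returns a strains × arrays DataFrame of mean signals over the (≤2)
    passing tags; strains with no passing tag are absent.
    """
    if quality is None:
        quality = background_filter(table)
    df = table.records[table.records["used"]]
    passing = quality[quality["passes_background"]][["strain_id", "tag"]]
    df = df.merge(passing, on=["strain_id", "tag"])
    return df.pivot_table(index="strain_id", columns="array_id",
                          values="signal", aggfunc="mean")


def best_tag_signal(table: TagIntensityTable, *,
                    best: pd.DataFrame | None = None,
                    report: QCReport | None = None) -> pd.DataFrame:
    """Strains × arrays signal matrix using each strain's best tag (HIPLAB-style)."""
    if best is None:
        best = select_best_tag(table, report=report)
    df = table.records[table.records["used"]]
    df = df.merge(best[["strain_id", "tag"]], on=["strain_id", "tag"])
    return df.pivot_table(index="strain_id", columns="array_id",
                          values="signal", aggfunc="first")


# ---------------------------------------------------------------------------
# log-ratios

def log2_ratio_hiplab(controls: pd.DataFrame, treatment: pd.Series) -> pd.Series:
    """HIPLAB convention: log2(median control signal / treatment signal) per strain.

    High values mean the strain lost abundance under treatment, i.e. a
    sensitive strain (``sensitivity_positive``).  Strains with any
    non-positive or missing signal are dropped.
    """
    med = controls.median(axis=1)
    common = med.index.intersection(treatment.index)
    med, trt = med.loc[common], treatment.loc[common]
    ok = (med > 0) & (trt > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("log2_ratio_hiplab: dropped %d strains with invalid signal", n_bad)
    return np.log2(med[ok] / trt[ok])


def log2_ratio_nibr(treatment_replicates: pd.DataFrame,
                    controls: pd.DataFrame) -> pd.Series:
    """NIBR convention: log2(mean treatment signal / mean control signal) per strain.

    Sensitive strains score negative (``sensitivity_negative``).
    """
    trt = treatment_replicates.mean(axis=1)
    ctl = controls.mean(axis=1)
    common = trt.index.intersection(ctl.index)
    trt, ctl = trt.loc[common], ctl.loc[common]
    ok = (trt > 0) & (ctl > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("log2_ratio_nibr: dropped %d strains with invalid signal", n_bad)
    return np.log2(trt[ok] / ctl[ok])


# ---------------------------------------------------------------------------
# standardization

def robust_z(matrix: ScreenMatrix, config: AnalysisConfig | None = None,
             report: QCReport | None = None) -> ScreenMatrix:
    """Per-screen robust z: (value − screen median) / screen MAD.

    This is the FD (fitness defect) / MADL score.  The MAD is unscaled by
    default (``config.mad_scaled`` applies the 1.4826 normal-consistency
    factor).  Screens with MAD = 0 or fewer than 3 finite values are
    degenerate: they are dropped from the output and listed in the QC report.
    Orientation is preserved.
    """
    config = config or AnalysisConfig()
    vals = matrix.values
    out = {}
    degenerate = []
    for col in vals.columns:
        x = vals[col].to_numpy(dtype=float)
        finite = x[~np.isnan(x)]
        if finite.size < 3:
            degenerate.append(str(col))
            continue
        med = float(np.median(finite))
        mad = _mad(finite, scaled=config.mad_scaled)
        if mad == 0:
            degenerate.append(str(col))
            continue
        out[col] = (vals[col] - med) / mad
    if degenerate:
        logger.warning("robust_z: %d degenerate screens excluded: %s",
                       len(degenerate), degenerate[:5])
        if report is not None:
            report.degenerate_screens.extend(degenerate)
    kind = "madl" if matrix.orientation == "sensitivity_negative" else "fd"
    return matrix.with_values(pd.DataFrame(out, index=vals.index), value_kind=kind)


def replicate_control_pvalues(treatment_replicates: pd.DataFrame,
                              controls: pd.DataFrame) -> pd.Series:
    """Per-strain Welch t-test P between treatment-replicate and control log2 signals."""
    common = treatment_replicates.index.intersection(controls.index)
    trt = np.log2(treatment_replicates.loc[common])
    ctl = np.log2(controls.loc[common])
    res = stats.ttest_ind(trt, ctl, axis=1, equal_var=False, nan_policy="omit")
    p = pd.Series(np.asarray(res.pvalue, dtype=float), index=common)
    return p


def adjust_madl(madl: ScreenMatrix, replicate_pvalues: pd.DataFrame,
                config: AnalysisConfig | None = None) -> ScreenMatrix:
    """Shrink MADL scores of strains whose replicates disagree with controls.

    Default ("capped") rule multiplies each entry by ``min(0.05/p, 1)`` where
    p is the strain-by-screen Welch t-test P between treatment replicates and
    controls; entries with p ≤ 0.05 are untouched, larger p shrink the score
    toward zero.  ``config.madl_adjustment = "pvalue"`` multiplies by p
    directly instead.  Missing p leaves the entry unchanged.
    The factor never exceeds 1, so |a_MADL| ≤ |MADL| entrywise.
    """
    config = config or AnalysisConfig()
    p = pd.DataFrame(replicate_pvalues).reindex(index=madl.values.index,
                                                columns=madl.values.columns)
    n_missing = int(p.isna().sum().sum())
    if n_missing:
        logger.info("adjust_madl: %d entries without replicate p, factor 1", n_missing)
    if config.madl_adjustment == "capped":
        factor = np.minimum(0.05 / p, 1.0)
    else:
        factor = p.copy()
    factor = factor.fillna(1.0)
    return madl.with_values(madl.values * factor, value_kind="a_madl")


def genewise_z_nibr(a_madl: ScreenMatrix, config: AnalysisConfig | None = None,
                    report: QCReport | None = None
                    ) -> tuple[ScreenMatrix, pd.DataFrame]:
    """NIBR gene-wise z: each strain's a_MADL divided by its robust spread σ.

    σ_i is the standard deviation of strain *i*'s a_MADL values lying within
    the central ``quantile_window`` (default 70%, i.e. 15th–85th percentile,
    inclusive, linear interpolation) across screens.  Strains with σ = 0 are
    flagged invariant and their z is missing.

    Returns the z matrix and a per-strain scale table
    ``(strain_id, sigma, n_used)``.
    """
    config = config or AnalysisConfig()
    vals = a_madl.values
    lo_q = (1.0 - config.quantile_window) / 2.0 * 100.0
    hi_q = 100.0 - lo_q
    sigmas, z_rows, scale_rows = {}, {}, []
    invariant = []
    for strain, row in vals.iterrows():
        x = row.to_numpy(dtype=float)
        finite = x[~np.isnan(x)]
        if finite.size < 2:
            invariant.append(str(strain))
            scale_rows.append((strain, math.nan, 0))
            continue
        lo, hi = np.percentile(finite, [lo_q, hi_q])
        central = finite[(finite >= lo) & (finite <= hi)]
        sigma = float(np.std(central, ddof=1)) if central.size >= 2 else 0.0
        scale_rows.append((strain, sigma, int(central.size)))
        if sigma == 0:
            invariant.append(str(strain))
            continue
        z_rows[strain] = row / sigma
    if invariant:
        logger.warning("genewise_z_nibr: %d invariant strains flagged", len(invariant))
        if report is not None:
            report.invariant_strains.extend(invariant)
    z = pd.DataFrame.from_dict(z_rows, orient="index", columns=vals.columns)
    z = z.reindex([s for s in vals.index if s in z_rows])
    scales = pd.DataFrame(scale_rows, columns=["strain_id", "sigma", "n_used"])
    return a_madl.with_values(z, value_kind="z"), scales


def genewise_z_hiplab(fd: ScreenMatrix, config: AnalysisConfig | None = None,
                      report: QCReport | None = None) -> ScreenMatrix:
    """HIPLAB gene-wise z: robust z of each strain's FDs across screens.

    (FD − strain median) / strain MAD, used to spot outlier screens per gene.
    Strains with MAD = 0 are flagged and dropped.
    """
    config = config or AnalysisConfig()
    vals = fd.values
    meds = vals.median(axis=1)
    mads = vals.sub(meds, axis=0).abs().median(axis=1)
    if config.mad_scaled:
        mads = mads * MAD_NORMAL_CONSISTENCY
    flagged = vals.index[(mads == 0) | mads.isna()]
    if len(flagged):
        logger.warning("genewise_z_hiplab: %d constant strains flagged", len(flagged))
        if report is not None:
            report.invariant_strains.extend(map(str, flagged))
    keep = vals.index.difference(flagged, sort=False)
    z = vals.loc[keep].sub(meds[keep], axis=0).div(mads[keep], axis=0)
    return fd.with_values(z, value_kind="z")


def significance_mask(matrix: ScreenMatrix,
                      config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Boolean mask of significant chemical-genetic interactions.

    ``sensitivity_positive`` (HIPLAB convention): one-tailed upper-tail
    standard-normal P ≤ alpha, i.e. value ≥ Φ⁻¹(1−alpha) (3.0902 at the
    default 0.001); boundary inclusive.  ``sensitivity_negative`` (NIBR
    convention): value < nibr_z_cutoff (default −5).  Missing values are
    never significant.
    """
    config = config or AnalysisConfig()
    if matrix.value_kind not in ("fd", "z", "madl", "a_madl"):
        raise ValueError(f"cannot assess significance of {matrix.value_kind!r} values")
    vals = matrix.values
    if matrix.orientation == "sensitivity_positive":
        thr = fd_significance_threshold(config.alpha_significant)
        mask = vals >= thr
    else:
        mask = vals < config.nibr_z_cutoff
    return mask.fillna(False).astype(bool)


def harmonize_orientation(matrix: ScreenMatrix) -> ScreenMatrix:
    """Flip ``sensitivity_negative`` matrices so that positive = sensitive.

    Multiplies by −1 and sets the flag; idempotent on already-positive input.
    This is the documented single point where the orientation flag changes.
    """
    if matrix.orientation == "sensitivity_positive":
        return matrix.copy()
    return matrix.with_values(-matrix.values, orientation="sensitivity_positive")


# ---------------------------------------------------------------------------
# whole-site pipelines

def score_hiplab(table: TagIntensityTable, config: AnalysisConfig | None = None
                 ) -> tuple[ScreenMatrix, QCReport]:
    """Full HIPLAB pipeline: polish → best tag → log2(median ctrl / trt) → robust z."""
    config = config or AnalysisConfig()
    report = QCReport()
    normed = median_polish_normalize(table)
    quality = background_filter(normed, report=report)
    best = select_best_tag(normed, quality=quality, report=report)
    signal = best_tag_signal(normed, best=best)
    arrays = normed.arrays
    ctrl_ids = arrays.loc[arrays["role"] == "control", "array_id"].tolist()
    trt_ids = arrays.loc[arrays["role"] == "treatment", "array_id"].tolist()
    controls = signal[[c for c in ctrl_ids if c in signal.columns]]
    ratios = {t: log2_ratio_hiplab(controls, signal[t])
              for t in trt_ids if t in signal.columns}
    lr = ScreenMatrix(pd.DataFrame(ratios), value_kind="raw_log2ratio",
                      orientation="sensitivity_positive")
    fd = robust_z(lr, config, report=report)
    return fd, report


def score_nibr(table: TagIntensityTable, replicate_groups: dict[str, list[str]],
               config: AnalysisConfig | None = None
               ) -> tuple[ScreenMatrix, pd.DataFrame, QCReport]:
    """Full NIBR pipeline: study normalize → tag average → log2(trt/ctrl) →
    robust z → replicate-adjusted a_MADL → gene-wise z.

    *replicate_groups* maps each screen id to its treatment array ids.
    Returns the gene-wise z matrix (``sensitivity_negative``), the per-strain
    σ table and the QC report.
    """
    config = config or AnalysisConfig()
    report = QCReport()
    normed = normalize_by_study(table)
    quality = background_filter(normed, report=report)
    signal = average_tags(normed, quality=quality)
    arrays = normed.arrays
    ctrl_ids = [c for c in arrays.loc[arrays["role"] == "control", "array_id"]
                if c in signal.columns]
    controls = signal[ctrl_ids]
    ratios, pvals = {}, {}
    for screen, reps in replicate_groups.items():
        reps = [r for r in reps if r in signal.columns]
        if not reps:
            report.warnings.append(f"screen {screen!r}: no replicate arrays present")
            continue
        trt = signal[reps]
        ratios[screen] = log2_ratio_nibr(trt, controls)
        pvals[screen] = replicate_control_pvalues(trt, controls)
    lr = ScreenMatrix(pd.DataFrame(ratios), value_kind="raw_log2ratio",
                      orientation="sensitivity_negative")
    madl = robust_z(lr, config, report=report)
    a_madl = adjust_madl(madl, pd.DataFrame(pvals), config)
    z, scales = genewise_z_nibr(a_madl, config, report=report)
    return z, scales, report
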