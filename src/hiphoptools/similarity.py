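"""Coinhibition and cofitness: the profile-correlation layer.

*Coinhibition* is the Pearson correlation between two screens' FD profiles
across strains — high values mean two compounds inhibit the same strains and
likely share a mechanism of action.  *Cofitness* is the transpose notion:
the Pearson correlation between two strains' FD profiles across screens —
high values mean two genes buffer the same perturbations and likely share
function.

For clustering, insignificant scores are first replaced by zero so the
correlation is driven by the confident chemical-genetic interactions rather
than by correlated noise; raw-profile correlation is also available.  All
correlations are pairwise-complete with a minimum-shared-observation floor,
below which the pair is reported missing.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import AnalysisConfig, ScreenMatrix
from .scoring import fd_significance_threshold, significance_mask

logger = logging.getLogger(__name__)


class SimilarityMatrix:
    """Symmetric Pearson similarity with per-pair shared-observation counts.

    ``axis`` is ``"screens"`` (coinhibition) or ``"genes"`` (cofitness).
    ``values`` is symmetric with unit diagonal where defined; entries backed
    by fewer than the configured minimum of pairwise-complete observations
    are missing, as are correlations involving constant profiles.
    """

    def __init__(self, values: pd.DataFrame, n_shared: pd.DataFrame, axis: str):
        if axis not in ("screens", "genes"):
            raise ValueError(f"unknown similarity axis {axis!r}")
        self.values = values
        self.n_shared = n_shared
        self.axis = axis

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    def distance(self, missing_value: float = 1.0) -> pd.DataFrame:
        """(1 − r) distance; missing pairs get *missing_value* (default 1,
        i.e. zero similarity — a neutral placement)."""
        d = 1.0 - self.values
        d = d.fillna(missing_value)
        np.fill_diagonal(d.to_numpy(), 0.0)
        return d


def zero_insignificant(matrix: ScreenMatrix,
                       config: AnalysisConfig | None = None) -> ScreenMatrix:
    """Replace insignificant scores with zero; significant and missing stay.

    Requires ``sensitivity_positive`` orientation; significance is the
    one-tailed standard-normal rule at ``config.alpha_significant``.
    Idempotent: zeros are themselves insignificant and stay zero.
    """
    config = config or AnalysisConfig()
    if matrix.orientation != "sensitivity_positive":
        raise ValueError("zero_insignificant expects sensitivity_positive input; "
                         "run harmonize_orientation first")
    mask = significance_mask(matrix, config)
    vals = matrix.values.where(mask, 0.0)
    vals = vals.where(matrix.values.notna())  # keep missing missing
    return matrix.with_values(vals)


def _pairwise_pearson(data: pd.DataFrame, min_shared: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson between columns of *data* + shared counts."""
    notna = data.notna().astype(float)
    n_shared = notna.T @ notna
    r = data.corr(method="pearson", min_periods=max(min_shared, 2))
    r = r.where(n_shared >= min_shared)
    # constant columns: pandas yields NaN already; ensure exact unit diagonal
    diag_ok = [c for c in data.columns
               if notna[c].sum() >= min_shared and data[c].std(skipna=True) > 0]
    for c in diag_ok:
        r.loc[c, c] = 1.0
    return r, n_shared.astype(int)


def coinhibition(matrix: ScreenMatrix, config: AnalysisConfig | None = None,
                 *, zero: bool = True) -> SimilarityMatrix:
    """Screen × screen Pearson correlation of FD profiles.

    With ``zero=True`` (the clustering default) insignificant scores are
    zeroed first; ``zero=False`` correlates the full raw profiles.  Pairs
    sharing fewer than ``config.min_shared_obs`` strains, and screens with
    zero variance after zeroing, come back missing.
    """
    config = config or AnalysisConfig()
    m = zero_insignificant(matrix, config) if zero else matrix
    r, n = _pairwise_pearson(m.values, config.min_shared_obs)
    n_constant = sum(m.values[c].std(skipna=True) == 0 for c in m.values.columns)
    if n_constant:
        logger.warning("coinhibition: %d zero-variance screens, correlations missing",
                       n_constant)
    return SimilarityMatrix(r, n, axis="screens")


def cofitness(matrix: ScreenMatrix, config: AnalysisConfig | None = None,
              *, zero: bool = False) -> SimilarityMatrix:
    """Gene × gene Pearson correlation of fitness profiles across screens."""
    config = config or AnalysisConfig()
    m = zero_insignificant(matrix, config) if zero else matrix
    r, n = _pairwise_pearson(m.values.T, config.min_shared_obs)
    return SimilarityMatrix(r, n, axis="genes")


def top_variable_genes(matrix: ScreenMatrix, fraction: float | None = None,
                       config: AnalysisConfig | None = None) -> list[str]:
    """Genes whose FD standard deviation across screens is in the top fraction.

    Ranked by pairwise-complete row SD; returns the top ``ceil(fraction * n)``
    gene ids (default fraction: ``config.top_variable_fraction`` = 5%).
    """
    config = config or AnalysisConfig()
    if fraction is None:
        fraction = config.top_variable_fraction
    sd = matrix.values.std(axis=1, skipna=True)
    n_top = math.ceil(fraction * len(sd))
    ranked = sd.sort_values(ascending=False, kind="stable")
    return [str(g) for g in ranked.index[:n_top]]


def cross_dataset_gene_correlation(mat_a: ScreenMatrix, mat_b: ScreenMatrix,
                                   shared_compounds: list[tuple[str, str]],
                                   config: AnalysisConfig | None = None
                                   ) -> tuple[pd.Series, dict]:
    """Per-gene Pearson r between the two datasets over paired compounds.

    *shared_compounds* lists (screen id in A, screen id in B) pairs profiling
    the same compound.  Both matrices must be harmonized to
    ``sensitivity_positive``.  Returns the per-gene r over shared genes and a
    summary with the overall median r and the median restricted to the
    top-variable genes (of the paired A sub-matrix).
    """
    config = config or AnalysisConfig()
    for m, name in ((mat_a, "A"), (mat_b, "B")):
        if m.orientation != "sensitivity_positive":
            raise ValueError(f"matrix {name} must be harmonized first")
    cols_a = [a for a, _ in shared_compounds]
    cols_b = [b for _, b in shared_compounds]
    genes = mat_a.values.index.intersection(mat_b.values.index)
    skipped = (len(mat_a.values.index) - len(genes),
               len(mat_b.values.index) - len(genes))
    sub_a = mat_a.values.loc[genes, cols_a]
    sub_b = mat_b.values.loc[genes, cols_b]
    sub_b.columns = sub_a.columns  # align paired screens positionally

    a = sub_a.to_numpy(dtype=float)
    b = sub_b.to_numpy(dtype=float)
    both = ~np.isnan(a) & ~np.isnan(b)
    r = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        m = both[i]
        if m.sum() < 3:
            continue
        xa, xb = a[i, m], b[i, m]
        if xa.std() == 0 or xb.std() == 0:
            continue
        r[i] = np.corrcoef(xa, xb)[0, 1]
    per_gene = pd.Series(r, index=genes, name="r")
    top = set(top_variable_genes(
        ScreenMatrix(sub_a, mat_a.value_kind, mat_a.orientation), config=config))
    summary = {
        "median_r_all": float(per_gene.median(skipna=True)),
        "median_r_top_variable": float(
            per_gene.loc[[g for g in genes if str(g) in top]].median(skipna=True)),
        "n_genes": int(per_gene.notna().sum()),
        "n_skipped_a": skipped[0],
        "n_skipped_b": skipped[1],
    }
    return per_gene, summary
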