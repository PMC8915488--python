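"""Cross-dataset operations: matrix merging and signature matching.

Signatures from two sites are compared by the Szymkiewicz–Simpson overlap
coefficient ``|A ∩ B| / min(|A|, |B|)`` between their characteristic gene
sets.  A signature counts as *detected* in the other dataset when its best
partner's overlap reaches the match threshold (default 0.5); matching is
best-partner, not one-to-one assignment, and the full overlap matrix is
always reported so other thresholds can be applied post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import AnalysisConfig, ScreenMatrix
from .signatures import ResponseSignature


def merge_datasets(mat_a: ScreenMatrix, mat_b: ScreenMatrix,
                   policy: str = "union") -> ScreenMatrix:
    """Column-concatenate two harmonized FD matrices.

    Both inputs must be ``sensitivity_positive`` and have disjoint screen
    ids (prefix them by site if needed).  ``policy="union"`` keeps every
    strain, with missing values where a strain is absent from one site;
    ``policy="intersect"`` keeps only shared strains.  The column count is
    always the sum of the inputs'.
    """
    for m, name in ((mat_a, "A"), (mat_b, "B")):
        if m.orientation != "sensitivity_positive":
            raise ValueError(f"matrix {name} must be harmonized to "
                             "sensitivity_positive before merging")
    overlap = set(mat_a.col_ids) & set(mat_b.col_ids)
    if overlap:
        raise ValueError(
            f"screen ids present in both matrices: {sorted(overlap)[:5]} — "
            "prefix screen ids by site before merging")
    if policy == "union":
        rows = mat_a.values.index.union(mat_b.values.index, sort=True)
    elif policy == "intersect":
        rows = mat_a.values.index.intersection(mat_b.values.index).sort_values()
    else:
        raise ValueError(f"unknown merge policy {policy!r}")
    merged = pd.concat([mat_a.values.reindex(rows), mat_b.values.reindex(rows)],
                       axis=1)
    return ScreenMatrix(merged, value_kind=mat_a.value_kind,
                        orientation="sensitivity_positive")


def split_merged(merged: ScreenMatrix, cols_a: list[str],
                 drop_missing_rows: bool = True) -> ScreenMatrix:
    """Recover one site's sub-matrix from a merged matrix."""
    sub = merged.values[cols_a]
    if drop_missing_rows:
        sub = sub.dropna(how="all")
    return merged.with_values(sub)


def overlap_coefficient(set_a, set_b) -> float:
    """Szymkiewicz–Simpson overlap: |A∩B| / min(|A|,|B|); 0 if either empty."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


@dataclass
class SignatureMatch:
    """Best cross-dataset partner of one response signature."""

    signature_a: int
    signature_b: int | None
    overlap: float
    shared_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"signature_a": self.signature_a, "signature_b": self.signature_b,
                "overlap": self.overlap, "shared_genes": list(self.shared_genes)}


@dataclass
class ComparisonReport:
    """Two-directional signature-matching summary between sites A and B."""

    matches_ab: list[SignatureMatch]
    matches_ba: list[SignatureMatch]
    matched_fraction_ab: float
    matched_fraction_ba: float
    exclusive_a: list[int]
    exclusive_b: list[int]
    overlap_matrix: pd.DataFrame
    shared_enrichment_pairs: list[tuple[int, int]] = field(default_factory=list)
    target_frequency: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "matched_fraction_ab": self.matched_fraction_ab,
            "matched_fraction_ba": self.matched_fraction_ba,
            "matches_ab": [m.to_dict() for m in self.matches_ab],
            "matches_ba": [m.to_dict() for m in self.matches_ba],
            "exclusive_a": self.exclusive_a,
            "exclusive_b": self.exclusive_b,
            "overlap_matrix": {
                "rows": [str(i) for i in self.overlap_matrix.index],
                "cols": [str(c) for c in self.overlap_matrix.columns],
                "values": self.overlap_matrix.to_numpy().tolist(),
            },
            "shared_enrichment_pairs": [list(p) for p in self.shared_enrichment_pairs],
            "target_frequency": self.target_frequency,
        }


def _best_matches(sigs_from: list[ResponseSignature],
                  sigs_to: list[ResponseSignature],
                  threshold: float) -> tuple[list[SignatureMatch], float, list[int]]:
    matches, exclusive = [], []
    n_matched = 0
    for sa in sigs_from:
        best, best_ov = None, -1.0
        for sb in sigs_to:
            ov = overlap_coefficient(sa.signature_genes, sb.signature_genes)
            if ov > best_ov:
                best, best_ov = sb, ov
        if best is None:
            matches.append(SignatureMatch(sa.cluster_id, None, 0.0))
            exclusive.append(sa.cluster_id)
            continue
        shared = sorted(set(sa.signature_genes) & set(best.signature_genes))
        matches.append(SignatureMatch(sa.cluster_id, best.cluster_id,
                                      best_ov, shared))
        if best_ov >= threshold:
            n_matched += 1
        else:
            exclusive.append(sa.cluster_id)
    frac = n_matched / len(sigs_from) if sigs_from else 0.0
    return matches, frac, exclusive


def match_signatures(sigs_a: list[ResponseSignature],
                     sigs_b: list[ResponseSignature],
                     config: AnalysisConfig | None = None) -> ComparisonReport:
    """Best-partner overlap matching of two signature collections.

    For every signature the best-overlapping partner in the other collection
    is recorded; it is *detected* there when the overlap reaches
    ``config.overlap_match_threshold``.  The report carries matched
    fractions in both directions, the site-exclusive signature ids, the full
    overlap-coefficient matrix, and the pairs that additionally share at
    least one enriched gene set (an alternative, annotation-level view of
    signature agreement).
    """
    config = config or AnalysisConfig()
    thr = config.overlap_match_threshold
    matches_ab, frac_ab, excl_a = _best_matches(sigs_a, sigs_b, thr)
    matches_ba, frac_ba, excl_b = _best_matches(sigs_b, sigs_a, thr)
    ov = pd.DataFrame(
        [[overlap_coefficient(sa.signature_genes, sb.signature_genes)
          for sb in sigs_b] for sa in sigs_a],
        index=[sa.cluster_id for sa in sigs_a],
        columns=[sb.cluster_id for sb in sigs_b])
    shared_enr = []
    for sa in sigs_a:
        ea = set(sa.enriched_sets())
        if not ea:
            continue
        for sb in sigs_b:
            if ea & set(sb.enriched_sets()):
                shared_enr.append((sa.cluster_id, sb.cluster_id))
    return ComparisonReport(
        matches_ab=matches_ab, matches_ba=matches_ba,
        matched_fraction_ab=frac_ab, matched_fraction_ba=frac_ba,
        exclusive_a=excl_a, exclusive_b=excl_b,
        overlap_matrix=ov, shared_enrichment_pairs=shared_enr)
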