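"""Synthetic two-site chemogenomic datasets with planted ground truth.

The generators emulate the statistical structure of the two real screening
collections so every downstream stage can be exercised against a known
answer:

* :func:`generate_fd_dataset` — two strain × screen FD matrices, one per
  site, with planted *response classes* (groups of replicate screens sharing
  a characteristic gene signature), planted single-gene HIP targets with a
  large clearance, opposite sign conventions between the sites
  (the NIBR-like site is ``sensitivity_negative``) and a block of strains
  dropped from the NIBR-like site (emulating the slow growers lost from the
  overnight-grown pools).
* :func:`generate_tag_intensities` — a raw barcode-array intensity table:
  per-strain log-normal control baselines, treatment arrays attenuating the
  planted sensitive strains multiplicatively by 2^(−log2 defect), a fraction
  of noisy ("bad") tags with inflated control variance, and unused
  background features at a low constant level.
* :func:`generate_fixture_gmt` — gene sets matching the planted signatures
  plus size-matched decoys, for exercising enrichment.

Everything is driven by one :class:`SimulationConfig` and a single seed;
outputs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ScreenMatrix, ScreenMeta, TagIntensityTable


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, on the scales the pipeline consumes.

    FD-scale parameters (``effect_size``, ``background_noise_sd``,
    ``target_effect``) are in robust-z units; intensity parameters are log2
    fluorescence units.  Defaults plant 8 response classes of 4 replicate
    screens each over 1000 strains, signature genes at mean FD 8 over unit
    noise, HIP targets at FD 12, and drop 50 strains from the NIBR-like
    site.
    """

    n_strains: int = 1000
    n_classes: int = 8
    replicate_range: tuple[int, int] = (4, 4)
    n_unstructured: int = 10          # classless screens per site
    signature_size_range: tuple[int, int] = (5, 15)
    effect_size: float = 8.0
    background_noise_sd: float = 1.0
    target_effect: float = 12.0
    n_target_genes: int = 3           # pool of genes reused as planted HIP targets
    dropout_count: int = 50           # strains absent from the NIBR-like site
    classes_site_a: tuple[int, ...] | None = None   # default: all classes
    classes_site_b: tuple[int, ...] | None = None
    # intensity model
    n_control_arrays: int = 6
    n_treatment_screens: int = 12
    n_replicate_arrays: int = 1       # treatment arrays per screen
    control_log_mean: float = 10.0    # log2 units
    control_log_sd: float = 1.0       # strain-to-strain baseline spread
    intensity_noise_sd: float = 0.15  # per-measurement log2 noise
    bad_tag_fraction: float = 0.1
    bad_tag_noise_factor: float = 5.0
    background_level: float = 6.0     # log2 level of unused features
    n_background_features: int = 50
    planted_defect: float = 2.0       # log2 fitness defect of intensity targets
    n_batches: int = 2
    batch_effect_sd: float = 0.3      # log2 batch offsets (removed by polish)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 0 or self.n_strains < 1:
            raise ValueError("invalid sizes")
        if self.n_classes * max(self.signature_size_range[1], 1) > self.n_strains:
            raise ValueError("n_classes x max signature size exceeds n_strains")
        if self.dropout_count >= self.n_strains:
            raise ValueError("dropout_count must be < n_strains")
        if not 0 <= self.bad_tag_fraction < 1:
            raise ValueError("bad_tag_fraction must be in [0,1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated dataset."""

    class_of_screen: dict[str, int] = field(default_factory=dict)   # 0 = none
    signature_genes: dict[int, list[str]] = field(default_factory=dict)
    planted_targets: dict[str, str] = field(default_factory=dict)
    site_of_screen: dict[str, str] = field(default_factory=dict)
    replicate_group: dict[str, str] = field(default_factory=dict)
    dropped_strains: list[str] = field(default_factory=list)
    replicate_arrays: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for cid, genes in self.signature_genes.items():
            if cid != 0 and not genes:
                raise ValueError(f"class {cid} has an empty signature")
        dropped = set(self.dropped_strains)
        for screen, target in self.planted_targets.items():
            if self.site_of_screen.get(screen) == "NIBR" and target in dropped:
                raise ValueError(
                    f"target {target} of NIBR screen {screen} is a dropped strain")


def _gene_ids(n: int, zygosity: str = "het") -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}:{zygosity}" for i in range(n)]


def generate_fd_dataset(config: SimulationConfig
                        ) -> tuple[dict[str, ScreenMatrix], ScreenMeta, SyntheticTruth]:
    """Two-site FD matrices with planted classes, targets and dropout.

    Returns ``({"HIPLAB": ScreenMatrix, "NIBR": ScreenMatrix}, meta, truth)``.
    The HIPLAB-like matrix is ``sensitivity_positive``; the NIBR-like matrix
    carries the same planted structure sign-flipped (``sensitivity_negative``)
    with ``dropout_count`` strains removed.  Replicate screens of one class
    share a compound label and differ only by noise; each unstructured screen
    carries one planted single-gene HIP target drawn from a small pool.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_strains)

    # disjoint signatures so planted classes are unambiguous
    sizes = rng.integers(config.signature_size_range[0],
                         config.signature_size_range[1] + 1,
                         size=config.n_classes)
    shuffled = list(rng.permutation(genes))
    signature: dict[int, list[str]] = {}
    pos = 0
    for k in range(1, config.n_classes + 1):
        signature[k] = sorted(shuffled[pos:pos + sizes[k - 1]])
        pos += sizes[k - 1]
    signature_genes_flat = {g for gs in signature.values() for g in gs}
    non_signature = [g for g in genes if g not in signature_genes_flat]
    target_pool = list(rng.choice(non_signature,
                                  size=min(config.n_target_genes, len(non_signature)),
                                  replace=False))

    # strains dropped from the NIBR-like site: uniform over non-target genes
    non_target = [g for g in genes if g not in target_pool]
    dropped = sorted(rng.choice(non_target, size=config.dropout_count,
                                replace=False)) if config.dropout_count else []

    classes_a = config.classes_site_a or tuple(range(1, config.n_classes + 1))
    classes_b = config.classes_site_b or tuple(range(1, config.n_classes + 1))

    truth = SyntheticTruth(signature_genes=signature, dropped_strains=list(dropped))
    meta_rows = []
    matrices: dict[str, ScreenMatrix] = {}

    for site, class_ids in (("HIPLAB", classes_a), ("NIBR", classes_b)):
        cols: dict[str, np.ndarray] = {}
        site_genes = [g for g in genes if site == "HIPLAB" or g not in dropped]
        gene_pos = {g: i for i, g in enumerate(site_genes)}
        for k in class_ids:
            n_rep = int(rng.integers(config.replicate_range[0],
                                     config.replicate_range[1] + 1))
            compound = f"cpd_class{k}"
            for r in range(n_rep):
                screen = f"{site}_c{k}_r{r}"
                x = rng.normal(0.0, config.background_noise_sd, len(site_genes))
                for g in signature[k]:
                    if g in gene_pos:
                        x[gene_pos[g]] += config.effect_size
                cols[screen] = x
                truth.class_of_screen[screen] = k
                truth.site_of_screen[screen] = site
                truth.replicate_group[screen] = f"{site}_rep_c{k}"
                meta_rows.append((screen, compound, 10.0, "uM", "HOP", site,
                                  f"{site}_rep_c{k}"))
        for u in range(config.n_unstructured):
            screen = f"{site}_u{u}"
            x = rng.normal(0.0, config.background_noise_sd, len(site_genes))
            target = target_pool[int(rng.integers(len(target_pool)))] \
                if target_pool else None
            if target is not None:
                x[gene_pos[target]] += config.target_effect
                truth.planted_targets[screen] = target
            cols[screen] = x
            truth.class_of_screen[screen] = 0
            truth.site_of_screen[screen] = site
            truth.replicate_group[screen] = screen
            meta_rows.append((screen, f"cpd_{site}_u{u}", 10.0, "uM", "HIP",
                              site, screen))
        values = pd.DataFrame(cols, index=site_genes)
        if site == "NIBR":
            matrices[site] = ScreenMatrix(-values, value_kind="fd",
                                          orientation="sensitivity_negative")
        else:
            matrices[site] = ScreenMatrix(values, value_kind="fd",
                                          orientation="sensitivity_positive")

    meta = ScreenMeta(pd.DataFrame(
        meta_rows, columns=["screen_id", "compound", "dose", "dose_unit",
                            "assay", "site", "replicate_group"]))
    truth.validate()
    return matrices, meta, truth


def generate_tag_intensities(config: SimulationConfig
                             ) -> tuple[TagIntensityTable, SyntheticTruth]:
    """Raw tag-intensity table with one planted sensitive strain per screen.

    Control arrays share per-(strain, tag) log-normal baselines; each
    treatment screen attenuates its planted target's signal by
    2^(−planted_defect) before multiplicative noise.  A ``bad_tag_fraction``
    of tags get their control noise inflated ``bad_tag_noise_factor``-fold
    (these are what best-tag selection should avoid).  Unused background
    features are emitted on every array at ``background_level``.  Arrays are
    spread over ``n_batches`` batches with log2 batch offsets that the
    median-polish step is expected to remove.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_strains)
    tags = ("up", "down")

    baseline = {}
    strain_level = rng.normal(config.control_log_mean, config.control_log_sd,
                              len(genes))
    for i, g in enumerate(genes):
        for t in tags:
            baseline[(g, t)] = strain_level[i] + rng.normal(0.0, 0.3)
    bad = {key: rng.random() < config.bad_tag_fraction for key in baseline}

    ctrl_arrays = [f"ctrl_{i}" for i in range(config.n_control_arrays)]
    trt_screens = [f"trt_{i}" for i in range(config.n_treatment_screens)]
    arrays = list(ctrl_arrays)
    replicate_arrays: dict[str, list[str]] = {}
    for s in trt_screens:
        replicate_arrays[s] = [f"{s}_rep{j}" for j in range(config.n_replicate_arrays)] \
            if config.n_replicate_arrays > 1 else [s]
        arrays += replicate_arrays[s]

    batch_of = {a: f"batch{idx % config.n_batches}" for idx, a in enumerate(arrays)}
    batch_shift = {f"batch{b}": rng.normal(0.0, config.batch_effect_sd)
                   for b in range(config.n_batches)}

    # one planted sensitive strain per treatment screen, all distinct
    targets = list(rng.choice(genes, size=len(trt_screens), replace=False))
    truth = SyntheticTruth(
        planted_targets=dict(zip(trt_screens, targets)),
        site_of_screen={s: "HIPLAB" for s in trt_screens},
        class_of_screen={s: 0 for s in trt_screens},
        replicate_group={s: s for s in trt_screens},
        replicate_arrays=replicate_arrays,
    )

    records = []
    for a in arrays:
        role = "control" if a in ctrl_arrays else "treatment"
        screen = None
        if role == "treatment":
            screen = next(s for s, reps in replicate_arrays.items() if a in reps)
        shift = batch_shift[batch_of[a]]
        for g in genes:
            for t in tags:
                mu = baseline[(g, t)] + shift
                sd = config.intensity_noise_sd
                if role == "control" and bad[(g, t)]:
                    sd *= config.bad_tag_noise_factor
                if role == "treatment" and truth.planted_targets[screen] == g:
                    mu -= config.planted_defect
                sig = float(np.power(2.0, mu + rng.normal(0.0, sd)))
                records.append((g, t, a, sig, role, batch_of[a], "study0", True))
        for b in range(config.n_background_features):
            sig = float(np.power(2.0, config.background_level + shift
                                 + rng.normal(0.0, config.intensity_noise_sd)))
            records.append((f"bg_{b:03d}", "up", a, sig, role, batch_of[a],
                            "study0", False))
    table = TagIntensityTable(pd.DataFrame(
        records, columns=["strain_id", "tag", "array_id", "signal", "role",
                          "batch", "study_id", "used"]))
    return table, truth


def generate_fixture_gmt(truth: SyntheticTruth, n_strains: int | None = None,
                         decoys_per_signature: int = 2,
                         seed: int = 0) -> dict[str, list[str]]:
    """Gene sets for enrichment tests: the planted signatures plus decoys.

    Emits one set per planted class (its exact signature genes) and, per
    class, ``decoys_per_signature`` size-matched sets drawn uniformly from
    the non-signature genes.
    """
    rng = np.random.default_rng(seed)
    classes = {k: v for k, v in truth.signature_genes.items() if k != 0}
    if not classes:
        raise ValueError("truth has no planted classes")
    sig_genes = {g for gs in classes.values() for g in gs}
    n = n_strains or max(len(sig_genes) * 5, 100)
    universe = _gene_ids(n)
    background = [g for g in universe if g not in sig_genes]
    sets: dict[str, list[str]] = {}
    for k, genes in sorted(classes.items()):
        sets[f"class_{k}"] = list(genes)
        for d in range(decoys_per_signature):
            sets[f"decoy_{k}_{d}"] = sorted(
                rng.choice(background, size=min(len(genes), len(background)),
                           replace=False))
    return sets


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Named study conditions: ``small`` (fast tests) or ``paperlike``
    (two sites sharing 6 of 9 planted classes, deeper strain dropout)."""
    if name == "small":
        return SimulationConfig(n_strains=200, n_classes=4, n_unstructured=4,
                                dropout_count=10, n_treatment_screens=6,
                                n_control_arrays=4, n_background_features=30,
                                seed=seed)
    if name == "paperlike":
        # 9 planted classes per site, 6 shared: matched fraction 6/9 = 66.7%
        return SimulationConfig(n_strains=1200, n_classes=12,
                                classes_site_a=(1, 2, 3, 4, 5, 6, 7, 8, 9),
                                classes_site_b=(1, 2, 3, 4, 5, 6, 10, 11, 12),
                                n_unstructured=10, dropout_count=60,
                                seed=seed)
    raise ValueError(f"unknown preset {name!r}")
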