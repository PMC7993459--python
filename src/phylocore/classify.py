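"""Niche-type classification and the end-to-end pipeline.

Maps the evidence triple (community classes, per-class neutral-model
verdict, per-class phylogenetic dispersion) to a niche-type label:

==================  ==============  ===========================
verdict             dispersion      label
==================  ==============  ===========================
neutral             clustered       neutral_phylo_niche
neutral             overdispersed   neutral_nonphylo_niche
subset_departure    (refit passes)  mixed_neutral_selective
global_departure    clustered       selective_phylo_niche
global_departure    over./random    other_interactions
anything else                       undecidable
==================  ==============  ===========================

The pipeline runs: beta-diversity classes -> per-class Sloan fit (with an
automatic refit excluding departing taxa on a subset departure) -> NTI
against the tree-wide pool -> per-class PCG search -> the decision table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import child_seed
from .beta import ClassPartition, beta_distance, find_classes
from .containers import AbundanceTable, SequenceSet, ValidationError
from .dispersion import DispersionResult, Z_THRESHOLD, beta_nti, nti
from .neutral import NeutralFitResult, refit_excluding, sloan_fit
from .pcg import DEFAULT_LADDER, PCGResult, pcg_per_class
from .simulate import NICHE_TYPES
from .tree import LabeledTree


@dataclass(frozen=True)
class NicheCall:
    """A niche-type label for one community class, with its evidence."""

    class_id: str
    label: str
    evidence: dict

    def __post_init__(self) -> None:
        if self.label not in NICHE_TYPES:
            raise ValidationError(f"unknown niche label {self.label!r}")


def classify(
    classes_exist: bool,
    verdict: str,
    dispersion: str,
    refit_neutral_after_exclusion: bool | None = None,
    class_id: str = "C1",
) -> NicheCall:
    """Total decision function over the enumerated evidence domain."""
    if verdict == "neutral":
        if dispersion == "clustered":
            label = "neutral_phylo_niche"
        elif dispersion == "overdispersed":
            label = "neutral_nonphylo_niche"
        else:
            label = "undecidable"
    elif verdict == "subset_departure":
        label = (
            "mixed_neutral_selective" if refit_neutral_after_exclusion else "undecidable"
        )
    elif verdict == "global_departure":
        if dispersion == "clustered":
            label = "selective_phylo_niche"
        elif dispersion in ("overdispersed", "random"):
            label = "other_interactions"
        else:
            label = "undecidable"
    else:
        label = "undecidable"
    return NicheCall(
        class_id=class_id,
        label=label,
        evidence={
            "classes_exist": classes_exist,
            "verdict": verdict,
            "dispersion": dispersion,
            "refit_neutral_after_exclusion": refit_neutral_after_exclusion,
        },
    )


@dataclass
class PipelineConfig:
    """Tunable parameters for every stage, with documented defaults."""

    metric: str = "bray_curtis"
    k_max: int = 8
    n_perm: int = 999
    alpha: float = 0.05
    min_silhouette: float = 0.25
    detection_limit: float | None = None
    ci_level: float = 0.95
    neutral_frac: float = 0.05
    global_frac: float = 0.5
    n_null: int = 999
    z_threshold: float = Z_THRESHOLD
    thresholds: tuple[float, ...] = DEFAULT_LADDER
    min_count: int = 1
    seed: int = 0


@dataclass
class ClassReport:
    fit: NeutralFitResult | None
    refit: NeutralFitResult | None
    dispersion: DispersionResult
    beta_dispersion: DispersionResult | None
    pcgs: PCGResult
    call: NicheCall


@dataclass
class PipelineReport:
    partition: ClassPartition
    per_class: dict[str, ClassReport]
    config: PipelineConfig

    @property
    def labels(self) -> dict[str, str]:
        return {cls: rep.call.label for cls, rep in self.per_class.items()}

    @property
    def decided(self) -> bool:
        return any(lab != "undecidable" for lab in self.labels.values())

    def to_dict(self) -> dict:
        def fitdict(fit: NeutralFitResult | None):
            if fit is None:
                return None
            return {
                "m_hat": fit.m_hat,
                "fit_quality": fit.fit_quality,
                "verdict": fit.verdict,
                "departing_taxa": fit.departing_taxa,
                "boundary": fit.boundary,
            }

        def dispdict(d: DispersionResult | None):
            if d is None:
                return None
            return {
                "mntd_observed": d.mntd_observed,
                "null_mean": d.null_mean,
                "null_sd": d.null_sd,
                "z": d.z,
                "call": d.call,
                "kind": d.kind,
            }

        return {
            "classes": {
                "k": self.partition.k,
                "status": self.partition.status,
                "p_value": self.partition.p_value,
                "labels": self.partition.labels,
            },
            "per_class": {
                cls: {
                    "fit": fitdict(rep.fit),
                    "refit": fitdict(rep.refit),
                    "dispersion": dispdict(rep.dispersion),
                    "beta_dispersion": dispdict(rep.beta_dispersion),
                    "pcgs": [
                        {
                            "pcg_id": p.pcg_id,
                            "threshold": p.threshold,
                            "members": list(p.members),
                            "representative": p.representative,
                        }
                        for p in rep.pcgs.pcgs
                    ],
                    "residual": rep.pcgs.residual,
                    "label": rep.call.label,
                    "evidence": rep.call.evidence,
                }
                for cls, rep in self.per_class.items()
            },
        }


def _check_ids(table: AbundanceTable, seqs: SequenceSet, tree: LabeledTree) -> None:
    taxa = set(table.taxa)
    tips = set(tree.tip_labels)
    if not taxa <= tips:
        diff = sorted(taxa - tips)
        raise ValidationError(f"table taxa missing from tree: {diff}")
    sdiff = taxa.symmetric_difference(seqs.ids)
    if sdiff:
        raise ValidationError(
            f"table/sequence id mismatch (symmetric difference): {sorted(sdiff)}"
        )


def run_pipeline(
    table: AbundanceTable,
    seqs: SequenceSet,
    tree: LabeledTree,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """Execute the full detection pipeline and classify each class.

    The tree may span more tips than the table (a regional pool); the NTI
    pool is the full tip set. Deterministic given ``config.seed``.
    """
    cfg = config or PipelineConfig()
    _check_ids(table, seqs, tree)

    dist = beta_distance(table, cfg.metric)
    partition = find_classes(
        dist,
        k_range=range(2, cfg.k_max + 1),
        n_perm=cfg.n_perm,
        alpha=cfg.alpha,
        min_silhouette=cfg.min_silhouette,
        seed=child_seed(cfg.seed, "classes"),
    )
    classes_exist = partition.k >= 2
    pool = sorted(tree.tip_labels)

    pcgs_by_class = pcg_per_class(seqs, table, partition, cfg.thresholds, cfg.min_count)

    per_class: dict[str, ClassReport] = {}
    for cls in partition.classes:
        sub = table.subset_samples(partition.samples_of(cls)).trim_zero_taxa()

        fit: NeutralFitResult | None
        refit: NeutralFitResult | None = None
        refit_ok: bool | None = None
        try:
            fit = sloan_fit(
                sub,
                detection_limit=cfg.detection_limit,
                ci_level=cfg.ci_level,
                neutral_frac=cfg.neutral_frac,
                global_frac=cfg.global_frac,
            )
            verdict = fit.verdict
        except ValidationError:
            fit = None
            verdict = "undecidable"
        if fit is not None and verdict == "subset_departure":
            refit = refit_excluding(
                sub,
                fit.departing_taxa,
                detection_limit=cfg.detection_limit,
                ci_level=cfg.ci_level,
                neutral_frac=cfg.neutral_frac,
                global_frac=cfg.global_frac,
            )
            refit_ok = refit.verdict == "neutral"

        class_taxa = sorted(sub.taxa)
        if len(class_taxa) >= 2:
            disp = nti(
                class_taxa,
                tree,
                pool=pool,
                n_null=cfg.n_null,
                seed=child_seed(cfg.seed, "nti", cls),
                z_threshold=cfg.z_threshold,
            )
        else:
            disp = DispersionResult(
                float("nan"), float("nan"), 0.0, float("nan"), "undefined", 0
            )

        beta_disp = _within_class_beta_nti(sub, tree, pool, cfg, cls)

        call = classify(classes_exist, verdict, disp.call, refit_ok, class_id=cls)
        per_class[cls] = ClassReport(fit, refit, disp, beta_disp, pcgs_by_class[cls], call)

    return PipelineReport(partition=partition, per_class=per_class, config=cfg)


def _within_class_beta_nti(
    sub: AbundanceTable,
    tree: LabeledTree,
    pool: list[str],
    cfg: PipelineConfig,
    cls: str,
    n_pairs: int = 5,
) -> DispersionResult | None:
    """Mean between-sample dispersion over a few sample pairs of one class.

    Reported as supporting evidence (homogeneous vs heterogeneous
    selection); the decision table consumes the within-community NTI.
    """
    samples = sub.samples
    if len(samples) < 2:
        return None
    rng = np.random.default_rng(child_seed(cfg.seed, "betanti", cls))
    pres = sub.presence()
    zs = []
    last = None
    for i in range(min(n_pairs, len(samples) * (len(samples) - 1) // 2)):
        s1, s2 = rng.choice(len(samples), size=2, replace=False)
        a = list(pres.index[pres.iloc[:, int(s1)]])
        b = list(pres.index[pres.iloc[:, int(s2)]])
        if not a or not b:
            continue
        last = beta_nti(
            a, b, tree, pool=pool, n_null=max(99, cfg.n_null // 5),
            seed=child_seed(cfg.seed, "betanti", cls, i), z_threshold=cfg.z_threshold,
        )
        if np.isfinite(last.z):
            zs.append(last.z)
    if not zs or last is None:
        return None
    zbar = float(np.mean(zs))
    if zbar <= -cfg.z_threshold:
        call = "clustered"
    elif zbar >= cfg.z_threshold:
        call = "overdispersed"
    else:
        call = "random"
    return DispersionResult(last.mntd_observed, last.null_mean, last.null_sd, zbar, call, last.n_null, "beta_nti")
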