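"""Synthetic microbial communities with known assembly processes.

Generates every input the detection pipeline consumes — phylogenies, trait
tables, marker sequences, and sample x taxon count tables — under scenarios
with a known ground truth: a four-species cartoon family (two genera G1/G2
inside family F, traits arising by conserved divergence, convergence or
horizontal transfer) and regional-pool generalizations of the same
scenarios at statistically useful sizes.

Assembly follows dispersal-limited neutral sampling: a sample's relative
abundances are Dirichlet with concentration depth*m*q (q the metacommunity
composition, m the migration rate), then multinomially read-sampled to
depth. Selective mechanisms layer on top of this neutral core:

* a fitness *advantage* w>1 shifts a taxon's expected share to
  p*w / sum(p*w) and additionally multiplies its concentration by w
  (reliable establishment) — the taxon is present more consistently than a
  neutral taxon of the same mean abundance, which is what an
  occupancy-abundance neutrality test can detect;
* a *gradient* filters each sample through Gaussian weights around
  per-species optima, so different samples favor different taxa and
  occupancies fall below neutral expectation community-wide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._rng import spawn
from .containers import AbundanceTable, NicheSpec, SequenceSet, TraitTable, ValidationError
from .tree import LabeledTree, TreeError


class SimulationError(RuntimeError):
    """Raised when a generator cannot satisfy its contract."""


# ---------------------------------------------------------------------------
# Jukes-Cantor helpers
# ---------------------------------------------------------------------------

def jc_expected_identity(d: float) -> float:
    """Expected sequence identity after Jukes-Cantor distance d."""
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)

def jc_distance(identity: float) -> float:
    """Inverse of :func:`jc_expected_identity`."""
    if not 0.25 < identity <= 1.0:
        raise ValidationError("identity must be in (0.25, 1]")
    return -0.75 * math.log((4.0 * identity - 1.0) / 3.0)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int,
    birth_rate: float,
    death_rate: float = 0.0,
    seed: int = 0,
    max_tries: int = 200,
) -> LabeledTree:
    """Ultrametric birth-death tree with exactly ``n_tips`` extant tips.

    Gillespie simulation from a root split; the process stops when the
    extant lineage count first reaches ``n_tips`` and all extant lineages
    are extended by one further exponential waiting time, so the tree is
    sampled "just before the next event". Extinct lineages are pruned.
    Deterministic given the seed.
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    if not birth_rate > death_rate >= 0:
        raise ValidationError("need birth_rate > death_rate >= 0")
    rng = spawn(seed, "tree", n_tips, birth_rate, death_rate)

    for _ in range(max_tries):
        root = TreeNode(length=0.0)
        c0, c1 = TreeNode(), TreeNode()
        root.extend([c0, c1])
        active: list[tuple[TreeNode, float]] = [(c0, 0.0), (c1, 0.0)]
        t = 0.0
        dead = 0
        failed = False
        while len(active) < n_tips:
            k = len(active)
            if k == 0:
                failed = True
                break
            total = k * (birth_rate + death_rate)
            t += rng.exponential(1.0 / total)
            idx = int(rng.integers(k))
            node, born = active.pop(idx)
            if rng.random() < birth_rate / (birth_rate + death_rate):
                node.length = t - born
                a, b = TreeNode(), TreeNode()
                node.extend([a, b])
                active.append((a, t))
                active.append((b, t))
            else:
                node.length = t - born
                node.name = f"dead{dead}"
                dead += 1
        if failed:
            continue
        t += rng.exponential(1.0 / (len(active) * (birth_rate + death_rate)))
        for i, (node, born) in enumerate(active):
            node.length = t - born
            node.name = f"live{i}"
        if dead:
            root = root.shear([node.name for node, _ in active])
            root.length = 0.0
        # canonical tip names in tree traversal order
        width = max(3, len(str(n_tips)))
        for i, tip in enumerate(root.tips()):
            tip.name = f"T{i + 1:0{width}d}"
        return LabeledTree(root)
    raise SimulationError(
        f"could not reach {n_tips} extant tips in {max_tries} tries "
        f"(birth={birth_rate}, death={death_rate})"
    )


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitEvent:
    """A trait-origination event placed on a branch of the tree.

    ``branch`` is where the trait is carried from (the recipient lineage for
    HGT); ``donor`` names the donating lineage and is required iff
    origin == "hgt".
    """

    trait_id: str
    function_id: str
    origin: str
    branch: str
    donor: str | None = None


def evolve_traits(tree: LabeledTree, events: list[TraitEvent], seed: int = 0) -> TraitTable:
    """Propagate trait events to tips.

    branch_conserved and convergent traits are carried by every tip
    descending from their branch; an HGT trait is carried by the recipient
    lineage's tips while its recorded origin branch is the donor lineage.
    The placement is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    del seed
    seen: set[str] = set()
    rows = []
    for ev in events:
        if ev.trait_id in seen:
            raise ValidationError(f"duplicate trait_id {ev.trait_id!r} with conflicting placement")
        seen.add(ev.trait_id)
        if ev.origin not in ("branch_conserved", "convergent", "hgt"):
            raise ValidationError(f"unknown origin {ev.origin!r}")
        if not tree.has_node(ev.branch):
            raise TreeError(f"event branch {ev.branch!r} not in tree")
        if ev.origin == "hgt":
            if ev.donor is None:
                raise ValidationError(f"hgt trait {ev.trait_id!r} needs a donor branch")
            if not tree.has_node(ev.donor):
                raise TreeError(f"donor branch {ev.donor!r} not in tree")
            recipient = set(tree.clade_tips(ev.branch))
            if set(tree.clade_tips(ev.donor)) >= recipient:
                raise ValidationError(
                    f"hgt trait {ev.trait_id!r}: donor lineage contains the recipient"
                )
            origin_branch = ev.donor
        else:
            origin_branch = ev.branch
        for tip in tree.clade_tips(ev.branch):
            rows.append(
                {
                    "species": tip,
                    "trait_id": ev.trait_id,
                    "function_id": ev.function_id,
                    "origin": ev.origin,
                    "origin_branch": origin_branch,
                }
            )
    return TraitTable(pd.DataFrame(rows, columns=["species", "trait_id", "function_id", "origin", "origin_branch"]))


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def evolve_sequences(tree: LabeledTree, length: int = 1200, seed: int = 0) -> SequenceSet:
    """Evolve one marker sequence per tip under Jukes-Cantor.

    A uniform-random root sequence is substituted along each branch with
    per-site probability 0.75*(1 - exp(-4*d/3)); substitutions pick one of
    the three other bases uniformly.
    """
    if length < 100:
        raise ValidationError("sequence length must be >= 100")
    rng = spawn(seed, "seq", length)
    root_seq = rng.integers(0, 4, size=length).astype(np.uint8)
    out: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            d = child.length or 0.0
            p_sub = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            new = seq.copy()
            if p_sub > 0:
                mask = rng.random(length) < p_sub
                n_sub = int(mask.sum())
                if n_sub:
                    new[mask] = (new[mask] + rng.integers(1, 4, size=n_sub)) % 4
            if child.is_tip():
                out[child.name] = new
            else:
                descend(child, new)

    descend(tree.root, root_seq)
    ids = tree.tip_labels
    return SequenceSet.from_matrix(ids, np.stack([out[i] for i in ids]))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _draw_composition(
    rng: np.random.Generator, q: np.ndarray, total_conc: float, conc_mult: np.ndarray
) -> np.ndarray:
    """One sample's relative abundances under dispersal-limited sampling.

    Plain taxa are jointly Dirichlet(total_conc * q). Taxa with a
    concentration multiplier != 1 are drawn first by stick-breaking Betas
    with their concentration scaled by the multiplier; with all multipliers
    at 1 this reduces exactly to the Dirichlet (aggregation property).
    """
    n = q.size
    x = np.zeros(n)
    adv = np.flatnonzero(conc_mult != 1.0)
    mass = 1.0
    mean_left = 1.0
    for i in adv:
        qi = float(np.clip(q[i] / mean_left, 1e-12, 1 - 1e-12))
        c = total_conc * conc_mult[i]
        xi = rng.beta(c * qi, c * (1.0 - qi))
        x[i] = mass * xi
        mass *= 1.0 - xi
        mean_left = max(mean_left - q[i], 1e-12)
    rest = np.setdiff1d(np.arange(n), adv, assume_unique=True)
    if rest.size:
        alpha = np.maximum(total_conc * q[rest], 1e-12)
        g = rng.gamma(alpha)
        s = g.sum()
        if s <= 0:  # underflow at extreme dispersal limitation: one winner
            g = np.zeros(rest.size)
            g[int(rng.integers(rest.size))] = 1.0
            s = 1.0
        x[rest] = mass * g / s
    else:
        s = x.sum()
        x = x / s if s > 0 else np.full(n, 1.0 / n)
    return x


def assemble_samples(
    tree: LabeledTree,
    traits: TraitTable,
    niche: NicheSpec,
    n_samples: int,
    depth: int,
    m: float,
    metacommunity_abundances: dict[str, float] | None = None,
    seed: int = 0,
    sample_prefix: str = "S",
    trim: bool = True,
) -> AbundanceTable:
    """Draw ``n_samples`` communities from one niche.

    Only species whose traits cover ``niche.required_traits`` can appear;
    each sample is a multinomial read sample (to ``depth``) of a
    dispersal-limited composition with migration ``m``. Deterministic given
    the seed.
    """
    if not 0 < m <= 1:
        raise ValidationError("migration m must be in (0, 1]")
    if n_samples < 1 or depth < 1:
        raise ValidationError("n_samples and depth must be positive")
    eligible = traits.covering(set(niche.required_traits))
    eligible = [sp for sp in eligible if sp in set(tree.tip_labels)]
    if not eligible:
        raise ValidationError(
            f"no species covers the required traits {sorted(niche.required_traits)}"
        )
    if niche.gradient is not None and len(niche.gradient) != n_samples:
        raise ValidationError("gradient must provide one position per sample")

    if metacommunity_abundances is None:
        p = np.full(len(eligible), 1.0 / len(eligible))
    else:
        p = np.array([float(metacommunity_abundances.get(sp, 0.0)) for sp in eligible])
        if p.sum() <= 0:
            raise ValidationError("metacommunity abundances sum to zero over eligible species")
        p = p / p.sum()

    w_adv = np.array([float(niche.advantage.get(sp, 1.0)) for sp in eligible])
    # advantage also stabilizes establishment; ``stabilized`` boosts
    # establishment without shifting the expected share
    conc_mult = w_adv * np.array([float(niche.stabilized.get(sp, 1.0)) for sp in eligible])
    if niche.gradient is not None:
        optima = np.array([float(niche.optima.get(sp, 0.5)) for sp in eligible])

    rng = spawn(seed, "assembly", n_samples, depth, m)
    width = max(3, len(str(n_samples)))
    counts = np.zeros((len(eligible), n_samples), dtype=np.int64)
    for s in range(n_samples):
        w = w_adv.copy()
        if niche.gradient is not None:
            g = float(niche.gradient[s])
            w = w * np.exp(-((g - optima) ** 2) / (2.0 * niche.gradient_sd**2))
        q = p * w
        if q.sum() <= 0:
            raise ValidationError(f"sample {s}: all eligible species filtered out")
        q = q / q.sum()
        x = _draw_composition(rng, q, depth * m, conc_mult)
        x = np.maximum(x, 0.0)
        x = x / x.sum()
        counts[:, s] = rng.multinomial(depth, x)

    df = pd.DataFrame(
        counts,
        index=eligible,
        columns=[f"{sample_prefix}{i + 1:0{width}d}" for i in range(n_samples)],
    )
    # species lacking the required traits appear with all-zero rows unless trimmed
    others = [sp for sp in traits.species if sp not in set(eligible) and sp in set(tree.tip_labels)]
    if others and not trim:
        zeros = pd.DataFrame(0, index=others, columns=df.columns, dtype=np.int64)
        df = pd.concat([df, zeros]).loc[sorted(df.index.tolist() + others)]
    table = AbundanceTable(df)
    return table.trim_zero_taxa() if trim else table


# ---------------------------------------------------------------------------
# The four-species cartoon family
# ---------------------------------------------------------------------------

#: Calibrated expected identities: genus pairs cluster at the 0.97 rung,
#: the whole family at the 0.92 rung.
WITHIN_GENUS_IDENTITY = 0.985
CROSS_GENUS_IDENTITY = 0.945

FIG_THRESHOLDS = {"species": 1.00, "genus": 0.97, "family": 0.92}


@dataclass(frozen=True)
class Fig1Fixture:
    tree: LabeledTree
    traits: TraitTable
    sequences: SequenceSet
    thresholds: dict[str, float]

    def __iter__(self):
        return iter((self.tree, self.traits, self.sequences))


def _fig_tree() -> LabeledTree:
    x = jc_distance(WITHIN_GENUS_IDENTITY) / 2.0
    y = (jc_distance(CROSS_GENUS_IDENTITY) - jc_distance(WITHIN_GENUS_IDENTITY)) / 2.0
    return LabeledTree.from_newick(
        f"((SA:{x:.8f},SB:{x:.8f})G1:{y:.8f},(SC:{x:.8f},SD:{x:.8f})G2:{y:.8f})F;"
    )


def _fig_events(case: str) -> list[TraitEvent]:
    events = [
        TraitEvent("rectangle", "grey", "branch_conserved", "F"),
        TraitEvent("triangle", "blue", "branch_conserved", "G1"),
        TraitEvent("diamond", "green", "branch_conserved", "G2"),
    ]
    if case == "B":
        events += [
            TraitEvent("star_a", "yellow", "convergent", "SA"),
            TraitEvent("star_b", "yellow", "hgt", "SB", donor="SC"),
            TraitEvent("star_c", "yellow", "convergent", "SC"),
            TraitEvent("star_d", "yellow", "convergent", "SD"),
        ]
    return events


def fig1_fixture(case: str, seq_length: int = 1200, seed: int = 0) -> Fig1Fixture:
    """The four-species family: tree, traits, and calibrated sequences.

    Family F splits into genera G1 (SA, SB) and G2 (SC, SD). Case A carries
    only conserved traits (rectangle on the root branch, triangle on G1,
    diamond on G2); case B adds four distinct star traits sharing the
    "yellow" function — convergent on SA, SC, SD and transferred
    horizontally to SB from the SC lineage. Branch lengths are calibrated so
    genus pairs exceed the 0.97 identity rung and cross-genus pairs fall
    between 0.92 and 0.97; a realized sequence draw violating these margins
    is redrawn (deterministically).
    """
    if case not in ("A", "B"):
        raise ValidationError(f"unknown case {case!r}; expected 'A' or 'B'")
    from .pcg import pairwise_identity  # local import: pcg does not import simulate

    tree = _fig_tree()
    traits = evolve_traits(tree, _fig_events(case))
    for attempt in range(50):
        seqs = evolve_sequences(tree, seq_length, seed=(seed + 1009 * attempt))
        ident = pairwise_identity(seqs)
        within = min(ident.loc["SA", "SB"], ident.loc["SC", "SD"])
        cross = [ident.loc[a, b] for a in ("SA", "SB") for b in ("SC", "SD")]
        if within >= 0.975 and max(cross) <= 0.965 and min(cross) >= 0.925:
            return Fig1Fixture(tree, traits, seqs, dict(FIG_THRESHOLDS))
    raise SimulationError("could not realize calibrated sequences; increase seq_length")


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

SCENARIOS = (1, 2, 3, 4, 5, 6, "selective", "niche_construction")

#: Fig. 2 niche-type vocabulary (shared with the classifier).
NICHE_TYPES = (
    "neutral_phylo_niche",
    "neutral_nonphylo_niche",
    "mixed_neutral_selective",
    "selective_phylo_niche",
    "other_interactions",
    "undecidable",
)


@dataclass(frozen=True)
class TruthLabels:
    """Ground truth recorded by the generator for scenario-recovery tests."""

    scenario: object
    case: str
    niche_type: str
    n_classes: int | None
    class_of_sample: dict[str, str] | None = None
    departing_taxa: tuple[str, ...] = ()
    expected_pcgs: tuple[frozenset, ...] | None = None
    eligible: tuple[str, ...] = ()
    ambiguous: bool = False


@dataclass
class Dataset:
    tree: LabeledTree
    traits: TraitTable
    sequences: SequenceSet
    table: AbundanceTable
    truth: TruthLabels


@dataclass(frozen=True)
class ScenarioParams:
    """Study conditions for scenario generation.

    With ``pool_size`` unset, scenarios 1-5 use the literal four-species
    family; scenarios 6, "selective" and "niche_construction" default to a
    regional pool of 256 tips in which the focal family is a clade (the
    statistical tests need taxon-rich communities and a pool strictly
    larger than the sampled niche). Unset fields take per-scenario
    defaults.
    """

    n_samples: int | None = None
    depth: int | None = None
    m: float | None = None
    pool_size: int | None = None
    seq_length: int = 1200
    lognormal_sigma: float = 1.5
    advantage: float = 5.0
    family_fraction: float = 0.4
    gradient_sd: float = 0.12
    n_advantaged: int | None = None  # taxa under selective advantage (scenario 6)
    n_esv: int = 1


_FIG_DEFAULTS = dict(n_samples=30, depth=300, m=0.0005)
_REGIONAL_DEFAULTS = {
    1: dict(n_samples=60, depth=1000, m=0.05),
    2: dict(n_samples=60, depth=1000, m=0.05),
    3: dict(n_samples=60, depth=1000, m=0.05),
    4: dict(n_samples=120, depth=1000, m=0.05),  # same effort per niche as scenario 1
    5: dict(n_samples=60, depth=1000, m=0.05),
    6: dict(n_samples=100, depth=1000, m=0.05),
    "selective": dict(n_samples=100, depth=1000, m=0.01),
    "niche_construction": dict(n_samples=60, depth=1000, m=0.05),
}


def _resolve(params: ScenarioParams, defaults: dict) -> ScenarioParams:
    fill = {k: v for k, v in defaults.items() if getattr(params, k) is None}
    return replace(params, **fill)


def _lognormal_abundances(rng: np.random.Generator, taxa: list[str], sigma: float) -> dict[str, float]:
    vals = rng.lognormal(0.0, sigma, size=len(taxa))
    vals /= vals.sum()
    return dict(zip(taxa, vals))


def _maximin_spread(tree: LabeledTree, k: int, candidates: list[str] | None = None) -> list[str]:
    """Greedy subset of k tips maximizing the minimum pairwise distance."""
    dmat = tree.patristic()
    cand = sorted(candidates if candidates is not None else tree.tip_labels)
    sub = dmat.loc[cand, cand].to_numpy()
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    chosen = [int(i), int(j)]
    while len(chosen) < min(k, len(cand)):
        mind = sub[:, chosen].min(axis=1)
        mind[chosen] = -1.0
        chosen.append(int(np.argmax(mind)))
    return sorted(cand[c] for c in chosen)


def _partition_clades(tree: LabeledTree, label: str, max_fraction: float = 0.3) -> list:
    """Split the clade under *label* into disjoint subclades.

    Clades larger than ``max_fraction`` of the focal clade are replaced by
    their children, yielding pieces small enough to balance into groups.
    """
    fam = tree.node(label)
    fam_n = sum(1 for _ in fam.tips())

    def size(node) -> int:
        return 1 if node.is_tip() else sum(1 for _ in node.tips())

    frontier = list(fam.children)
    out: list = []
    while frontier:
        node = frontier.pop()
        if not node.is_tip() and size(node) > max_fraction * fam_n:
            frontier.extend(node.children)
        else:
            out.append(node)
    return out


def _regional_family_tree(params: ScenarioParams, seed: int) -> LabeledTree:
    """A regional pool tree with an internal clade labeled F (genera G1, G2).

    Branch lengths are rescaled so the family's deepest internal pair sits
    at ~0.94 expected identity, anchoring the identity ladder.
    """
    pool = params.pool_size or 256
    target = params.family_fraction * pool
    lo, hi = 0.2 * pool, 0.6 * pool
    for attempt in range(60):
        tree = simulate_tree(pool, 1.0, 0.0, seed=seed + 7919 * attempt)
        best, best_score = None, None
        for node in tree.root.non_tips(include_self=False):
            ntips = sum(1 for _ in node.tips())
            if not lo <= ntips <= hi or len(node.children) != 2:
                continue
            if any(c.is_tip() or sum(1 for _ in c.tips()) < 5 for c in node.children):
                continue
            score = abs(ntips - target)
            if best_score is None or score < best_score:
                best, best_score = node, score
        if best is None:
            continue
        best.name = "F"
        best.children[0].name = "G1"
        best.children[1].name = "G2"
        fam = [t.name for t in best.tips()]
        maxd = tree.patristic().loc[fam, fam].to_numpy().max()
        return LabeledTree(tree.root).scaled(jc_distance(0.94) / maxd)
    raise SimulationError("no suitable family clade found in regional pool")


def _fig_dataset(scenario, case: str, params: ScenarioParams, seed: int) -> Dataset:
    fx = fig1_fixture(case, params.seq_length, seed=seed)
    tree, traits = fx.tree, fx.traits
    n, depth, m = params.n_samples, params.depth, params.m
    fam = frozenset(("SA", "SB", "SC", "SD"))
    g1, g2 = frozenset(("SA", "SB")), frozenset(("SC", "SD"))

    def run(required, advantage=None, n_samples=n, prefix="S", sub_seed=0):
        niche = NicheSpec(frozenset(required), advantage=advantage or {})
        return assemble_samples(
            tree, traits, niche, n_samples, depth, m,
            seed=seed + sub_seed, sample_prefix=prefix,
        )

    if scenario == 1:
        table = run({"rectangle"})
        truth = TruthLabels(scenario, case, "neutral_phylo_niche", 1,
                            expected_pcgs=(fam,), eligible=tuple(sorted(fam)))
    elif scenario == 2:
        table = run({"triangle"})
        truth = TruthLabels(scenario, case, "neutral_phylo_niche", 1,
                            expected_pcgs=(g1,), eligible=tuple(sorted(g1)))
    elif scenario == 3:
        table = run({"diamond"})
        truth = TruthLabels(scenario, case, "neutral_phylo_niche", 1,
                            expected_pcgs=(g2,), eligible=tuple(sorted(g2)))
    elif scenario == 4:
        t1 = run({"triangle"}, n_samples=n // 2, prefix="N1_S", sub_seed=1)
        t2 = run({"diamond"}, n_samples=n - n // 2, prefix="N2_S", sub_seed=2)
        df = pd.concat([t1.df, t2.df], axis=1).fillna(0).astype(np.int64)
        table = AbundanceTable(df.loc[sorted(df.index)])
        classes = {s: "N1" for s in t1.samples} | {s: "N2" for s in t2.samples}
        truth = TruthLabels(scenario, case, "neutral_phylo_niche", 2,
                            class_of_sample=classes, expected_pcgs=(g1, g2),
                            eligible=tuple(sorted(fam)))
    elif scenario == 5:
        table = run({"yellow"})
        truth = TruthLabels(scenario, case, "neutral_nonphylo_niche", 1,
                            eligible=tuple(sorted(fam)), ambiguous=True)
    elif scenario == 6:
        table = run({"yellow"}, advantage={"SA": params.advantage})
        truth = TruthLabels(scenario, case, "mixed_neutral_selective", 1,
                            departing_taxa=("SA",), eligible=tuple(sorted(fam)))
    else:  # pragma: no cover - guarded by generate_scenario
        raise ValidationError(f"scenario {scenario!r} has no four-species mode")
    return Dataset(tree, traits, fx.sequences.subset(table.taxa), table, truth)


def _regional_dataset(scenario, case: str, params: ScenarioParams, seed: int) -> Dataset:
    rng = spawn(seed, "regional", scenario)
    tree = _regional_family_tree(params, seed=seed)
    events = _fig_events("A")[:3]  # conserved rectangle/triangle/diamond on F/G1/G2
    family = sorted(tree.clade_tips("F"))
    n, depth, m = params.n_samples, params.depth, params.m

    advantage: dict[str, float] = {}
    niche_required: set[str]
    p: dict[str, float]
    gradient = None
    optima = None
    truth_kwargs: dict = {}

    if scenario in (1, 2, 3, 4, 5):
        if scenario == 1:
            niche_required = {"rectangle"}
            p = _lognormal_abundances(rng, family, params.lognormal_sigma)
            truth_kwargs = dict(niche_type="neutral_phylo_niche", n_classes=1)
        elif scenario in (2, 3):
            genus = "G1" if scenario == 2 else "G2"
            niche_required = {"triangle" if scenario == 2 else "diamond"}
            tips = sorted(tree.clade_tips(genus))
            p = _lognormal_abundances(rng, tips, params.lognormal_sigma)
            truth_kwargs = dict(niche_type="neutral_phylo_niche", n_classes=1)
        elif scenario == 5:
            carriers = _maximin_spread(tree, 32)
            events = events + [
                TraitEvent(f"star_{t}", "yellow", "convergent", t) for t in carriers
            ]
            niche_required = {"yellow"}
            p = _lognormal_abundances(rng, carriers, params.lognormal_sigma)
            truth_kwargs = dict(niche_type="neutral_nonphylo_niche", n_classes=1)
        else:  # scenario 4: two genus niches sampled
            traits = evolve_traits(tree, events)
            tips1 = sorted(tree.clade_tips("G1"))
            tips2 = sorted(tree.clade_tips("G2"))
            p1 = _lognormal_abundances(rng, tips1, params.lognormal_sigma)
            p2 = _lognormal_abundances(rng, tips2, params.lognormal_sigma)
            t1 = assemble_samples(tree, traits, NicheSpec(frozenset({"triangle"})),
                                  n // 2, depth, m, p1, seed=seed + 1, sample_prefix="N1_S")
            t2 = assemble_samples(tree, traits, NicheSpec(frozenset({"diamond"})),
                                  n - n // 2, depth, m, p2, seed=seed + 2, sample_prefix="N2_S")
            df = pd.concat([t1.df, t2.df], axis=1).fillna(0).astype(np.int64)
            table = AbundanceTable(df.loc[sorted(df.index)])
            classes = {s: "N1" for s in t1.samples} | {s: "N2" for s in t2.samples}
            truth = TruthLabels(scenario, case, "neutral_phylo_niche", 2,
                                class_of_sample=classes, eligible=tuple(family))
            seqs = evolve_sequences(tree, params.seq_length, seed=seed).subset(table.taxa)
            return Dataset(tree, traits, seqs, table, truth)
    elif scenario == 6:
        pvals = _lognormal_abundances(rng, family, params.lognormal_sigma)
        ranked = sorted(family, key=lambda t: pvals[t])
        # the advantaged guild sits in the rare-to-intermediate prevalence
        # band, where an occupancy excess is detectable (abundant taxa are
        # saturated at occupancy 1 regardless of selection)
        n_adv = params.n_advantaged if params.n_advantaged is not None else 8
        n_adv = max(1, min(n_adv, len(ranked)))
        qs = np.linspace(0.15, 0.45, n_adv) if n_adv > 1 else np.array([0.25])
        idx = sorted({int(round(q * (len(ranked) - 1))) for q in qs})
        while len(idx) < n_adv:  # de-duplicate collisions on tiny families
            extra = (idx[-1] + 1) % len(ranked)
            if extra not in idx:
                idx.append(extra)
        chosen = [ranked[i] for i in idx[:n_adv]]
        tree = tree.rename_tips({chosen[0]: "SA"})
        family = sorted(tree.clade_tips("F"))
        pvals["SA"] = pvals.pop(chosen[0])
        chosen[0] = "SA"
        donor_pool = [t for t in family if t != "SA"]
        events = events + [
            TraitEvent(f"star_{t}", "yellow", "hgt" if t == "SA" else "convergent",
                       t, donor=donor_pool[0] if t == "SA" else None)
            for t in family
        ]
        niche_required = {"yellow"}
        p = pvals
        advantage = {t: params.advantage for t in chosen}
        truth_kwargs = dict(niche_type="mixed_neutral_selective", n_classes=1,
                            departing_taxa=tuple(sorted(chosen)))
    elif scenario == "selective":
        # Homogeneous strong selection with graded intensity: family
        # subclades differ in how reliably their specialized traits let
        # them establish (establishment concentration x1 / x10 / x100), so
        # no single migration rate can fit the occupancy-abundance
        # relation and neutrality is rejected community-wide. Selection
        # also evens out regional abundances (narrower lognormal).
        niche_required = {"rectangle"}
        p = _lognormal_abundances(rng, family, 0.8)
        clades = sorted(
            _partition_clades(tree, "F"),
            key=lambda nd: -(1 if nd.is_tip() else sum(1 for _ in nd.tips())),
        )
        groups: list[list[str]] = [[], [], []]
        for nd in clades:  # balance three intensity tiers over whole clades
            i = int(np.argmin([len(g) for g in groups]))
            tips = [nd.name] if nd.is_tip() else [t.name for t in nd.tips()]
            groups[i].extend(tips)
        for gi, fn in ((1, "armor_weak"), (2, "armor_strong")):
            events = events + [
                TraitEvent(f"{fn}_{t}", fn, "convergent", t) for t in groups[gi]
            ]
        stabilized = {t: 10.0 for t in groups[1]} | {t: 100.0 for t in groups[2]}
        truth_kwargs = dict(niche_type="selective_phylo_niche", n_classes=None,
                            departing_taxa=tuple(sorted(groups[0] + groups[2])))
        traits = evolve_traits(tree, events)
        niche = NicheSpec(frozenset(niche_required), stabilized=stabilized)
        table = assemble_samples(tree, traits, niche, n, depth, m, p, seed=seed + 3)
        truth = TruthLabels(scenario, case, eligible=tuple(sorted(p)), **truth_kwargs)
        seqs = evolve_sequences(tree, params.seq_length, seed=seed).subset(table.taxa)
        return Dataset(tree, traits, seqs, table, truth)
    elif scenario == "niche_construction":
        carriers = _maximin_spread(tree, 16)
        guild_a, guild_b = carriers[::2], carriers[1::2]
        events = events + [
            TraitEvent(f"fa_{t}", "fA", "convergent", t) for t in guild_a
        ] + [TraitEvent(f"fb_{t}", "fB", "convergent", t) for t in guild_b]
        traits = evolve_traits(tree, events)
        pa = _lognormal_abundances(rng, guild_a, params.lognormal_sigma)
        pb = _lognormal_abundances(rng, guild_b, params.lognormal_sigma)
        taxa = guild_a + guild_b
        base = np.array([pa[t] for t in guild_a] + [pb[t] for t in guild_b])
        counts = np.zeros((len(taxa), n), dtype=np.int64)
        for s in range(n):
            u = rng.beta(100, 100)  # tight complementary split between guilds
            noise = rng.lognormal(0.0, 0.3, size=len(taxa))
            x = base * noise
            x[: len(guild_a)] *= u / x[: len(guild_a)].sum()
            x[len(guild_a):] *= (1 - u) / x[len(guild_a):].sum()
            counts[:, s] = rng.multinomial(depth, x / x.sum())
        width = max(3, len(str(n)))
        table = AbundanceTable(pd.DataFrame(
            counts, index=taxa, columns=[f"S{i + 1:0{width}d}" for i in range(n)]
        ).loc[sorted(taxa)]).trim_zero_taxa()
        truth = TruthLabels(scenario, case, "other_interactions", 1,
                            eligible=tuple(sorted(taxa)), ambiguous=True)
        seqs = evolve_sequences(tree, params.seq_length, seed=seed).subset(table.taxa)
        return Dataset(tree, traits, seqs, table, truth)
    else:  # pragma: no cover
        raise ValidationError(f"unknown scenario {scenario!r}")

    traits = evolve_traits(tree, events)
    niche = NicheSpec(
        frozenset(niche_required), advantage=advantage,
        gradient=gradient, optima=optima, gradient_sd=params.gradient_sd,
    )
    table = assemble_samples(tree, traits, niche, n, depth, m, p, seed=seed + 3)
    truth = TruthLabels(scenario, case, eligible=tuple(sorted(p)), **truth_kwargs)
    seqs = evolve_sequences(tree, params.seq_length, seed=seed).subset(table.taxa)
    return Dataset(tree, traits, seqs, table, truth)


def generate_scenario(
    scenario, case: str = "A", params: ScenarioParams | None = None, seed: int = 0
) -> Dataset:
    """Generate a full dataset (tree, traits, sequences, counts, truth).

    Scenarios 1-4 sample conserved-trait niches of the family/genera;
    scenario 5 a convergent (nonphylo) function; scenario 6 adds a fitness
    advantage on species SA; "selective" applies a steep environmental
    gradient; "niche_construction" couples complementary guilds across
    distant clades. Scenarios 5, 6 require case B. Deterministic given seed.
    """
    if isinstance(scenario, str) and scenario.isdigit():
        scenario = int(scenario)
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if case not in ("A", "B"):
        raise ValidationError(f"unknown case {case!r}; expected 'A' or 'B'")
    if scenario in (5, 6) and case != "B":
        raise ValidationError(f"scenario {scenario} requires case B (star traits)")
    params = params or ScenarioParams()
    regional = params.pool_size is not None or scenario in (
        6, "selective", "niche_construction",
    )
    if regional:
        params = _resolve(params, {**_REGIONAL_DEFAULTS[scenario], "pool_size": 256})
        return _regional_dataset(scenario, case, params, seed)
    params = _resolve(params, _FIG_DEFAULTS)
    return _fig_dataset(scenario, case, params, seed)


# ---------------------------------------------------------------------------
# Convenience generators for the statistical tests
# ---------------------------------------------------------------------------

def neutral_dataset(
    n_taxa: int = 150,
    n_samples: int = 200,
    depth: int = 2000,
    m: float = 0.1,
    sigma: float = 2.0,
    seed: int = 0,
) -> tuple[AbundanceTable, dict[str, float], LabeledTree]:
    """A purely neutral community over a simulated tree.

    All taxa carry one root-conserved trait and are sampled from a
    lognormal metacommunity by dispersal-limited neutral assembly; used for
    migration-rate recovery and verdict type-I-error checks.
    """
    tree = simulate_tree(n_taxa, 1.0, 0.0, seed=seed)
    traits = evolve_traits(tree, [TraitEvent("core", "core", "branch_conserved", "root")])
    rng = spawn(seed, "meta", n_taxa, sigma)
    p = _lognormal_abundances(rng, sorted(tree.tip_labels), sigma)
    table = assemble_samples(
        tree, traits, NicheSpec(frozenset({"core"})), n_samples, depth, m, p, seed=seed
    )
    return table, p, tree


def add_esv_variants(
    sequences: SequenceSet,
    table: AbundanceTable,
    k: int,
    seed: int = 0,
    max_subs: int = 2,
) -> tuple[SequenceSet, AbundanceTable]:
    """Split each taxon into k exact sequence variants (<= max_subs apart).

    Variant relative frequencies are fixed per taxon (Dirichlet weights)
    and counts are split multinomially per sample.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k == 1:
        return sequences, table
    rng = spawn(seed, "esv", k)
    new_seqs: dict[str, np.ndarray] = {}
    rows = {}
    for taxon in table.taxa:
        base = sequences.matrix[sequences.ids.index(taxon)]
        weights = rng.dirichlet(np.full(k, 5.0))
        for j in range(k):
            var = base.copy()
            if j > 0:
                pos = rng.choice(len(var), size=int(rng.integers(1, max_subs + 1)), replace=False)
                var[pos] = (var[pos] + rng.integers(1, 4, size=len(pos))) % 4
            new_seqs[f"{taxon}.v{j + 1}"] = var
        counts = table.df.loc[taxon].to_numpy()
        split = np.stack([rng.multinomial(c, weights) for c in counts], axis=1)
        for j in range(k):
            rows[f"{taxon}.v{j + 1}"] = split[j]
    ids = list(rows)
    new_table = AbundanceTable(pd.DataFrame(rows, index=table.samples).T)
    return (
        SequenceSet.from_matrix(ids, np.stack([new_seqs[i] for i in ids])),
        new_table,
    )

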