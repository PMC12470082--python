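"""Synthetic CpG-island erosion: sequences evolving along a known clock tree
with methylation-like CpG hypermutability.

The model is an exact event-driven (Gillespie) simulation on the plus
strand, no indels, so the leaf sequences are aligned by construction:

* every site carries a background substitution rate ``mu`` per unit branch
  length, split among the three alternative bases with transitions favored
  by ``kappa`` (rate kappa : 1 : 1);
* every C whose right neighbor is G gains an extra C→T rate
  ``mu * (lambda_cpg - 1)``, and every G whose left neighbor is C gains an
  extra G→A rate of the same size — the strand-symmetric signature of
  methylated-CpG deamination, producing TpG (sense) and CpA (antisense);
* dinucleotide contexts are re-evaluated after every event, so erosion
  removes its own substrate.

With ``lambda_cpg`` in the empirically motivated 10–50× range this yields
CpG-dense islands whose CpG positions erode much faster than the
background, the regime the analysis pipeline is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .annotate import CladePartition
from .seqio import Msa, SequenceRecord, concatenate_loci
from .trees import ClockTree, Node

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
BASES = "ACGT"

# non-CG dinucleotide fillers for root construction: GC-rich, none starts
# with G (so no CpG can arise across unit boundaries), none contains CG
_FILLERS = ("CC", "CT", "AC", "TC", "CA")
_FILLER_WEIGHTS = (0.4, 0.15, 0.15, 0.15, 0.15)


@dataclass
class ErosionParams:
    """Simulation parameters.

    mu          background substitution rate, events per site per unit
                branch length (branch lengths are in Ma for the study tree;
                0.00015/Ma keeps the deepest pairwise divergence of the
                ~29 Ma primate-like tree below ~5% even with lambda_cpg=25
                erosion at the CpG sites, i.e. ≥95% pairwise identity)
    lambda_cpg  CpG hypermutability multiplier, ≥1 (10–50 plausible; 25 default)
    kappa       transition/transversion rate ratio for background events
    root_length bases in the root sequence
    cpg_fraction  target CpG dinucleotides per base at the root (≤0.5;
                0.085 mimics an island where ~17% of tiled dinucleotides
                are CpG)
    seed        master seed; every random stream derives from it
    """

    mu: float = 0.00015
    lambda_cpg: float = 25.0
    kappa: float = 2.0
    root_length: int = 5000
    cpg_fraction: float = 0.085
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.lambda_cpg < 1:
            raise ValueError("lambda_cpg must be >= 1")
        if not (0 <= self.cpg_fraction <= 0.5):
            raise ValueError("cpg_fraction must be in [0, 0.5]")
        if self.root_length < 2:
            raise ValueError("root_length must be >= 2")


@dataclass
class Event:
    branch: str          # label of the child node of the branch
    site: int            # 0-based site on the (possibly concatenated) sequence
    time: float          # time since the start of the branch
    from_base: str
    to_base: str
    context: str         # left+base+right trinucleotide just before the event
    channel: str         # "background" or "deamination"


@dataclass
class SimResult:
    tree: ClockTree
    root: SequenceRecord
    sequences: list[SequenceRecord]
    events: list[Event]

    def events_tsv(self) -> str:
        lines = ["branch\tsite\ttime\tfrom\tto\tcontext\tchannel"]
        for e in self.events:
            lines.append(f"{e.branch}\t{e.site}\t{e.time:.6g}\t{e.from_base}"
                         f"\t{e.to_base}\t{e.context}\t{e.channel}")
        return "\n".join(lines) + "\n"


@dataclass
class TruthAnnotations:
    """Ground-truth CpG position sets read directly off the leaf sequences
    (frame-0 dinucleotide tiling; independent of the annotation module)."""

    cpg_positions: set[int]
    conserved_cpg: set[int]
    variable_cpg: set[int]
    clade_markers: set[int]


@dataclass
class StudyDataset:
    params: ErosionParams
    tree: ClockTree
    partition: CladePartition
    locus_names: tuple[str, ...]
    records_by_locus: dict[str, dict[str, SequenceRecord]]
    sim: SimResult                 # concatenated loci
    msa: Msa                       # identity alignment of the leaf sequences
    truth: TruthAnnotations


# ---------------------------------------------------------------------------
# Root sequence
# ---------------------------------------------------------------------------

def make_root_sequence(params: ErosionParams, record_id: str = "root") -> SequenceRecord:
    """Island-like root: GC-rich, with round(cpg_fraction * length) CpG
    dinucleotides placed at frame-0 dinucleotide units; deterministic in
    ``params.seed``. Fillers never start with G and contain no CG, so the
    CpG count is exact and cpg_fraction 0 yields a CpG-free sequence."""
    rng = np.random.default_rng([params.seed, 0])
    L = params.root_length
    n_units = L // 2
    n_cpg = round(params.cpg_fraction * L)
    if n_cpg > n_units:
        raise ValueError(
            f"cpg_fraction {params.cpg_fraction} infeasible for length {L}"
        )
    cpg_units = set(rng.choice(n_units, size=n_cpg, replace=False).tolist())
    units = [
        "CG" if u in cpg_units
        else _FILLERS[rng.choice(len(_FILLERS), p=_FILLER_WEIGHTS)]
        for u in range(n_units)
    ]
    seq = "".join(units)
    if L % 2:
        seq += "T"
    gc = (seq.count("C") + seq.count("G")) / L
    if gc < 0.5:  # vanishingly unlikely at the default filler weights
        raise RuntimeError(f"root sequence GC {gc:.3f} below 0.5; adjust fillers")
    return SequenceRecord(id=record_id, seq=seq)


# ---------------------------------------------------------------------------
# Event-driven evolution
# ---------------------------------------------------------------------------

def _site_rate(seq: list[str], i: int, p: ErosionParams) -> float:
    b = seq[i]
    r = p.mu
    if b == "C" and i + 1 < len(seq) and seq[i + 1] == "G":
        r += p.mu * (p.lambda_cpg - 1)
    elif b == "G" and i > 0 and seq[i - 1] == "C":
        r += p.mu * (p.lambda_cpg - 1)
    return r


def evolve_branch(seq: str, t: float, params: ErosionParams,
                  rng: np.random.Generator, branch_label: str = "branch",
                  site_offset: int = 0) -> tuple[str, list[Event]]:
    """Evolve one sequence along one branch of length ``t``; returns the
    derived sequence and the chronological event log."""
    s = list(seq)
    L = len(s)
    p = params
    rates = np.array([_site_rate(s, i, p) for i in range(L)])
    total = float(rates.sum())
    events: list[Event] = []
    clock = 0.0
    tv_w = p.mu / (p.kappa + 2)
    ts_w = p.mu * p.kappa / (p.kappa + 2)
    while True:
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            break
        # pick the site proportionally to its rate
        u = rng.random() * total
        i = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        i = min(i, L - 1)
        b = s[i]
        # channel and target base
        extra = rates[i] - p.mu
        targets = [x for x in BASES if x != b]
        weights = [ts_w if x == TRANSITION[b] else tv_w for x in targets]
        deam_target = None
        if extra > 0:
            deam_target = "T" if b == "C" else "A"
            weights = [w + (extra if x == deam_target else 0.0)
                       for x, w in zip(targets, weights)]
        w = np.array(weights)
        pick = rng.choice(3, p=w / w.sum())
        to = targets[pick]
        channel = "deamination" if (
            deam_target is not None and to == deam_target
            and rng.random() < extra / (extra + (ts_w if to == TRANSITION[b] else tv_w))
        ) else "background"
        left = s[i - 1] if i > 0 else "."
        right = s[i + 1] if i + 1 < L else "."
        events.append(Event(branch=branch_label, site=i + site_offset,
                            time=clock, from_base=b, to_base=to,
                            context=left + b + right, channel=channel))
        s[i] = to
        for j in range(max(0, i - 1), min(L, i + 2)):
            rates[j] = _site_rate(s, j, p)
        total = float(rates.sum())
    return "".join(s), events


def _label_nodes(tree: ClockTree) -> None:
    """Give every internal node a stable label (preorder index) so branches
    can be named in the event log."""
    k = 0

    def walk(node: Node) -> None:
        nonlocal k
        if node.label is None:
            node.label = f"n{k}"
        k += 1
        for c in node.children:
            walk(c)

    walk(tree.root)


def evolve(root: SequenceRecord, tree: ClockTree, params: ErosionParams,
           rng: np.random.Generator | None = None) -> SimResult:
    """Evolve the root sequence down every branch of the tree."""
    bad = set(root.seq) - set(BASES)
    if bad:
        raise ValueError(f"root sequence must be over ACGT, found {sorted(bad)}")
    if rng is None:
        rng = np.random.default_rng([params.seed, 1])
    _label_nodes(tree)
    leaf_seqs: dict[str, str] = {}
    events: list[Event] = []

    def walk(node: Node, seq: str) -> None:
        for child in node.children:
            t = node.height - child.height
            if t < 0:
                raise ValueError("tree heights not monotone toward the root")
            if t == 0:
                child_seq, ev = seq, []
            else:
                child_seq, ev = evolve_branch(seq, t, params, rng,
                                              branch_label=child.label)
            events.extend(ev)
            if child.is_leaf:
                leaf_seqs[child.label] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.root, root.seq)
    sequences = [SequenceRecord(id=lab, seq=leaf_seqs[lab])
                 for lab in tree.leaf_labels()]
    return SimResult(tree=tree, root=root, sequences=sequences, events=events)


def replay_events(sim: SimResult) -> dict[str, str]:
    """Re-derive every leaf sequence by applying the logged events along the
    tree; used to verify the event log is a complete account of the run."""
    by_branch: dict[str, list[Event]] = {}
    for e in sim.events:
        by_branch.setdefault(e.branch, []).append(e)
    for evs in by_branch.values():
        evs.sort(key=lambda e: e.time)
    leaves: dict[str, str] = {}

    def walk(node: Node, seq: str) -> None:
        for child in node.children:
            s = list(seq)
            for e in by_branch.get(child.label, ()):
                if s[e.site] != e.from_base:
                    raise AssertionError(
                        f"event log inconsistent at branch {e.branch} site {e.site}"
                    )
                s[e.site] = e.to_base
            cs = "".join(s)
            if child.is_leaf:
                leaves[child.label] = cs
            else:
                walk(child, cs)

    walk(sim.tree.root, sim.root.seq)
    return leaves


# ---------------------------------------------------------------------------
# Study-like dataset
# ---------------------------------------------------------------------------

HOMINIDS = ("hg38", "AltaiNea", "Denisova", "panTro6", "panPan3",
            "gorGor6", "ponAbe3")
OLD_WORLD_MONKEYS = ("rheMac10", "macFas5", "papAnu4", "chlSab2", "rhiRox1")

CALIBRATION_PAIR = ("panTro6", "panPan3")
CALIBRATION_TIME_MA = 1.7


def primate_tree() -> ClockTree:
    """A 12-taxon primate-like clock tree, heights in Ma (chimp–bonobo split
    at 1.7 Ma, hominid–Old World monkey root at 29 Ma)."""

    def leaf(lab: str) -> Node:
        return Node(height=0.0, label=lab)

    def join(h: float, *nodes: Node) -> Node:
        return Node(height=h, children=list(nodes))

    humans = join(0.65, leaf("hg38"), join(0.45, leaf("AltaiNea"), leaf("Denisova")))
    apes = join(9.0, join(6.0, humans, join(1.7, leaf("panTro6"), leaf("panPan3"))),
                leaf("gorGor6"))
    hominids = join(14.0, apes, leaf("ponAbe3"))
    cerco = join(11.5, join(8.0, join(5.0, leaf("rheMac10"), leaf("macFas5")),
                            leaf("papAnu4")), leaf("chlSab2"))
    owm = join(16.2, cerco, leaf("rhiRox1"))
    return ClockTree(root=join(29.0, hominids, owm))


def study_partition() -> CladePartition:
    return CladePartition(name_a="hominids", members_a=frozenset(HOMINIDS),
                          name_b="old_world_monkeys",
                          members_b=frozenset(OLD_WORLD_MONKEYS))


def random_clock_tree(labels: Sequence[str], rng: np.random.Generator,
                      height: float = 1.0) -> ClockTree:
    """Random ultrametric topology over ``labels``: random pair merges at
    sorted uniform heights (a simple coalescent-style clock tree)."""
    nodes = [Node(height=0.0, label=l) for l in labels]
    hs = np.sort(rng.uniform(0, height, size=len(nodes) - 1))
    # enforce strictly increasing heights so every merge is resolvable
    for k in range(1, len(hs)):
        if hs[k] <= hs[k - 1]:
            hs[k] = hs[k - 1] + 1e-6 * height
    for h in hs:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(height=float(h), children=[a, b]))
    return ClockTree(root=nodes[0])


def two_clade_tree(partition: CladePartition, rng: np.random.Generator,
                   clade_height: float = 0.55, root_height: float = 1.0) -> ClockTree:
    a = random_clock_tree(sorted(partition.members_a), rng, height=clade_height)
    b = random_clock_tree(sorted(partition.members_b), rng, height=clade_height)
    return ClockTree(root=Node(height=root_height, children=[a.root, b.root]))


def _truth_from_leaves(leaf_seqs: dict[str, str],
                       partition: CladePartition) -> TruthAnnotations:
    L = len(next(iter(leaf_seqs.values())))
    cpg, cons, var, markers = set(), set(), set(), set()
    for k in range(L // 2):
        states = {sp: seq[2 * k: 2 * k + 2] for sp, seq in leaf_seqs.items()}
        has = [st == "CG" for st in states.values()]
        if not any(has):
            continue
        cpg.add(k)
        if all(has):
            cons.add(k)
            continue
        var.add(k)
        a = [states[s] == "CG" for s in partition.members_a]
        b = [states[s] == "CG" for s in partition.members_b]
        if (all(a) and not any(b)) or (all(b) and not any(a)):
            markers.add(k)
    return TruthAnnotations(cpg_positions=cpg, conserved_cpg=cons,
                            variable_cpg=var, clade_markers=markers)


DEFAULT_LOCUS_LENGTHS = (1700, 1600, 1700)
DEFAULT_LOCUS_NAMES = ("OCT4", "SOX2", "hTERT")


def generate_study_like_dataset(
    params: ErosionParams | None = None,
    n_taxa: int = 12,
    two_clades: CladePartition | None = None,
    tree: ClockTree | None = None,
    locus_lengths: Sequence[int] = DEFAULT_LOCUS_LENGTHS,
    locus_names: Sequence[str] = DEFAULT_LOCUS_NAMES,
) -> StudyDataset:
    """Simulate the full study design: three island loci evolved along a
    two-clade clock tree, concatenated per species, plus ground-truth CpG
    position sets.

    The default emulates the study conditions: 12 primate-like taxa
    (7 hominids vs 5 Old World monkeys), ~5000 concatenated island bases,
    CpG-context transitions at ``lambda_cpg`` times the background rate,
    and ≥95% pairwise identity at the default ``mu``. Locus lengths must be
    even so concatenation preserves the dinucleotide tiling frame.
    """
    params = params or ErosionParams()
    if any(l % 2 for l in locus_lengths):
        raise ValueError("locus lengths must be even to preserve the tiling frame")
    if len(locus_lengths) != len(locus_names):
        raise ValueError("locus_lengths and locus_names differ in length")
    if tree is None:
        if n_taxa == 12:
            tree = primate_tree()
            two_clades = two_clades or study_partition()
        else:
            if two_clades is None:
                half = n_taxa // 2
                two_clades = CladePartition(
                    name_a="clade_a",
                    members_a=frozenset(f"A{i}" for i in range(half)),
                    name_b="clade_b",
                    members_b=frozenset(f"B{i}" for i in range(n_taxa - half)),
                )
            rng = np.random.default_rng([params.seed, 2])
            # scale to the study tree's depth so default mu stays appropriate
            tree = two_clade_tree(two_clades, rng, clade_height=16.0,
                                  root_height=29.0)
    elif two_clades is None:
        raise ValueError("a clade partition is required when a tree is supplied")
    _label_nodes(tree)

    leaf_ids = tree.leaf_labels()
    records_by_locus: dict[str, dict[str, SequenceRecord]] = {s: {} for s in leaf_ids}
    all_events: list[Event] = []
    root_parts: list[str] = []
    offset = 0
    for j, (lname, llen) in enumerate(zip(locus_names, locus_lengths)):
        p_j = replace(params, root_length=int(llen), seed=params.seed + j)
        root_j = make_root_sequence(p_j, record_id=f"root_{lname}")
        sim_j = evolve(root_j, tree, p_j)
        root_parts.append(root_j.seq)
        for rec in sim_j.sequences:
            records_by_locus[rec.id][lname] = SequenceRecord(
                id=rec.id, seq=rec.seq, source_locus=lname)
        for e in sim_j.events:
            all_events.append(replace(e, site=e.site + offset))
        offset += llen

    concat = concatenate_loci(records_by_locus, order=list(locus_names))
    root = SequenceRecord(id="root", seq="".join(root_parts))
    sim = SimResult(tree=tree, root=root, sequences=concat, events=all_events)
    msa = Msa(ids=[r.id for r in concat], rows=[r.seq for r in concat])
    truth = _truth_from_leaves({r.id: r.seq for r in concat}, two_clades)
    return StudyDataset(params=params, tree=tree, partition=two_clades,
                        locus_names=tuple(locus_names),
                        records_by_locus=records_by_locus,
                        sim=sim, msa=msa, truth=truth)
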