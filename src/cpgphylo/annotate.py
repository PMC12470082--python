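"""Orthologous dinucleotide annotation of a multiple sequence alignment.

The alignment is tiled into non-overlapping column pairs ("orthologous
dinucleotide positions"), each position is classified by its CpG
conservation pattern across species, and summary statistics are derived:
variability counts, the CG→XY substitution spectrum, clade-distinguishing
marker positions, and guanine-context substitution counts for a pair of
species.

Evaluability rules, applied uniformly:
  * a species with a gap or N in either column of a position is not
    evaluable there (n_evaluable decreases);
  * if any species shows a gap run of length ≥2 touching either column,
    the whole position is excluded;
  * positions with fewer than 2 evaluable species are excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal

from .seqio import Msa


class PositionClass(str, Enum):
    CONSERVED_CPG = "conserved_cpg"
    VARIABLE_CPG = "variable_cpg"
    NONCPG_CONSERVED = "noncpg_conserved"
    NONCPG_VARIABLE = "noncpg_variable"
    EXCLUDED = "excluded"


@dataclass
class DinucPosition:
    """One orthologous dinucleotide position (two adjacent alignment columns)."""

    index: int
    columns: tuple[int, int]
    states: dict[str, str]  # species -> 2-char state over {A,C,G,T,N,-}²
    n_evaluable: int = 0
    klass: PositionClass | None = None

    def evaluable_states(self) -> dict[str, str]:
        return {s: st for s, st in self.states.items() if _evaluable(st)}


def _evaluable(state: str) -> bool:
    return not (set(state) & {"-", "N"})


@dataclass
class DinucPositionTable:
    ids: list[str]
    positions: list[DinucPosition]
    n_cols: int  # alignment length the table was tiled from

    def by_class(self, klass: PositionClass) -> list[DinucPosition]:
        return [p for p in self.positions if p.klass == klass]

    def class_counts(self) -> Counter:
        return Counter(p.klass for p in self.positions)

    def to_tsv(self) -> str:
        header = ["index", "col_start", "col_end", "class", "n_evaluable"] + list(self.ids)
        lines = ["\t".join(header)]
        for p in self.positions:
            row = [str(p.index), str(p.columns[0]), str(p.columns[1] + 1),
                   p.klass.value if p.klass else "", str(p.n_evaluable)]
            row += [p.states[s] for s in self.ids]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


@dataclass
class VariabilityStats:
    n_dinuc_positions: int
    n_cpg_positions: int
    n_conserved_cpg: int
    n_variable_cpg: int
    n_noncpg_variable_nt: int
    n_nt_positions: int
    fractions: dict[str, float] = field(default_factory=dict)

    def report(self) -> str:
        f = self.fractions
        return (
            f"dinucleotide positions analyzed: {self.n_dinuc_positions}\n"
            f"orthologous CpG positions:       {self.n_cpg_positions}\n"
            f"  variable in >=1 species:       {self.n_variable_cpg}"
            f" ({100 * f['variable_cpg_of_cpg']:.0f}% of CpG positions,"
            f" {100 * f['variable_cpg_of_dinuc']:.1f}% of all dinucleotides)\n"
            f"  fully conserved:               {self.n_conserved_cpg}"
            f" ({100 * f['conserved_cpg_of_cpg']:.0f}%)\n"
            f"non-CpG variable nucleotides:    {self.n_noncpg_variable_nt}"
            f" ({100 * f['noncpg_variable_of_nt']:.1f}% of {self.n_nt_positions}"
            f" nucleotide positions)\n"
        )


@dataclass
class SubstitutionSpectrum:
    """Counts of alternative dinucleotide states at variable CpG positions.

    The counting unit is the unique (position, alternative state) pair: an
    alternative carried by several species still counts once.
    """

    counts: Counter

    def total(self) -> int:
        return sum(self.counts.values())

    def sorted_items(self) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_tsv(self) -> str:
        lines = ["substitution\tcount"]
        lines += [f"CG->{alt}\t{n}" for alt, n in self.sorted_items()]
        return "\n".join(lines) + "\n"


@dataclass
class CladePartition:
    name_a: str
    members_a: frozenset[str]
    name_b: str
    members_b: frozenset[str]

    def __post_init__(self) -> None:
        self.members_a = frozenset(self.members_a)
        self.members_b = frozenset(self.members_b)
        if not self.members_a or not self.members_b:
            raise ValueError("both clades must be non-empty")
        if self.members_a & self.members_b:
            raise ValueError(
                f"clades overlap: {sorted(self.members_a & self.members_b)}"
            )


@dataclass
class ContextCounts:
    """Substituted-base counts between two species, keyed by the dinucleotide
    context (left neighbor + altered base) on the reference row, split into
    guanine vs non-guanine changes. ``cpa_adenine`` tallies altered adenines
    sitting in CpA context, the antisense signature of CpG deamination."""

    g_changes: Counter
    non_g_changes: Counter

    @property
    def cpa_adenine(self) -> int:
        return self.non_g_changes.get("CA", 0)

    def total(self) -> int:
        return sum(self.g_changes.values()) + sum(self.non_g_changes.values())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def tile_dinucleotides(msa: Msa) -> DinucPositionTable:
    """Tile the alignment into floor(n_cols/2) non-overlapping column pairs
    anchored at column 0; a trailing odd column is ignored."""
    if msa.n_cols < 2:
        raise ValueError("alignment has fewer than 2 columns")
    n_pos = msa.n_cols // 2
    positions = [
        DinucPosition(
            index=k,
            columns=(2 * k, 2 * k + 1),
            states={sid: row[2 * k: 2 * k + 2] for sid, row in zip(msa.ids, msa.rows)},
        )
        for k in range(n_pos)
    ]
    return DinucPositionTable(ids=list(msa.ids), positions=positions, n_cols=msa.n_cols)


def _gap_run_ge2(row: str, col: int) -> bool:
    """True if the gap at row[col] belongs to a run of length ≥2."""
    if row[col] != "-":
        return False
    left = col > 0 and row[col - 1] == "-"
    right = col + 1 < len(row) and row[col + 1] == "-"
    return left or right


def classify_positions(table: DinucPositionTable, msa: Msa) -> DinucPositionTable:
    """Assign a conservation class to every position (in place; returned for
    chaining). The Msa is needed to see gap runs extending beyond the
    position's own two columns."""
    rows = {sid: msa.row(sid) for sid in table.ids}
    for p in table.positions:
        c0, c1 = p.columns
        excluded = False
        for sid in table.ids:
            row = rows[sid]
            if _gap_run_ge2(row, c0) or _gap_run_ge2(row, c1):
                excluded = True
                break
        ev = p.evaluable_states()
        p.n_evaluable = len(ev)
        if excluded or p.n_evaluable < 2:
            p.klass = PositionClass.EXCLUDED
            continue
        states = set(ev.values())
        if states == {"CG"}:
            p.klass = PositionClass.CONSERVED_CPG
        elif "CG" in states:
            p.klass = PositionClass.VARIABLE_CPG
        elif len(states) == 1:
            p.klass = PositionClass.NONCPG_CONSERVED
        else:
            p.klass = PositionClass.NONCPG_VARIABLE
    return table


def _require_classified(table: DinucPositionTable) -> None:
    if any(p.klass is None for p in table.positions):
        raise ValueError("table must be classified first (run classify_positions)")


def variability_stats(table: DinucPositionTable, msa: Msa) -> VariabilityStats:
    """Counts and fractions of CpG vs non-CpG variability.

    ``n_noncpg_variable_nt`` counts alignment columns outside CpG-class
    positions where at least two distinct non-gap, non-N bases occur.
    """
    _require_classified(table)
    cc = table.class_counts()
    n_dinuc = len(table.positions)
    n_cons = cc.get(PositionClass.CONSERVED_CPG, 0)
    n_var = cc.get(PositionClass.VARIABLE_CPG, 0)
    n_cpg = n_cons + n_var

    cpg_cols = set()
    for p in table.positions:
        if p.klass in (PositionClass.CONSERVED_CPG, PositionClass.VARIABLE_CPG):
            cpg_cols.update(p.columns)
    n_noncpg_var = 0
    for col in range(msa.n_cols):
        if col in cpg_cols:
            continue
        bases = {row[col] for row in msa.rows} - {"-", "N"}
        if len(bases) >= 2:
            n_noncpg_var += 1

    n_nt = msa.n_cols
    fr = {
        "variable_cpg_of_cpg": n_var / n_cpg if n_cpg else 0.0,
        "conserved_cpg_of_cpg": n_cons / n_cpg if n_cpg else 0.0,
        "variable_cpg_of_dinuc": n_var / n_dinuc if n_dinuc else 0.0,
        "noncpg_variable_of_nt": n_noncpg_var / n_nt if n_nt else 0.0,
    }
    return VariabilityStats(
        n_dinuc_positions=n_dinuc, n_cpg_positions=n_cpg,
        n_conserved_cpg=n_cons, n_variable_cpg=n_var,
        n_noncpg_variable_nt=n_noncpg_var, n_nt_positions=n_nt, fractions=fr,
    )


def substitution_spectrum(table: DinucPositionTable) -> SubstitutionSpectrum:
    """CG→XY counts over variable CpG positions, one count per unique
    (position, alternative state) pair."""
    _require_classified(table)
    counts: Counter = Counter()
    for p in table.by_class(PositionClass.VARIABLE_CPG):
        for alt in sorted(set(p.evaluable_states().values()) - {"CG"}):
            counts[alt] += 1
    return SubstitutionSpectrum(counts=counts)


def clade_markers(table: DinucPositionTable, partition: CladePartition,
                  mode: Literal["cpg", "snv"] = "cpg") -> list[int]:
    """Positions whose states uniformly separate the two clades.

    mode "cpg": variable-CpG positions where every evaluable member of one
    clade is CG and every evaluable member of the other is not (either
    polarity). Returns dinucleotide position indices.

    mode "snv": single alignment columns within non-CpG positions where the
    two clades carry disjoint base sets and each clade is internally
    uniform. Returns column indices.
    """
    _require_classified(table)
    known = set(table.ids)
    missing = (partition.members_a | partition.members_b) - known
    if missing:
        raise KeyError(f"partition species absent from table: {sorted(missing)}")

    if mode == "cpg":
        hits = []
        for p in table.by_class(PositionClass.VARIABLE_CPG):
            ev = p.evaluable_states()
            a = [ev[s] for s in partition.members_a if s in ev]
            b = [ev[s] for s in partition.members_b if s in ev]
            if not a or not b:
                continue
            a_all_cpg, b_all_cpg = all(x == "CG" for x in a), all(x == "CG" for x in b)
            a_none, b_none = all(x != "CG" for x in a), all(x != "CG" for x in b)
            if (a_all_cpg and b_none) or (b_all_cpg and a_none):
                hits.append(p.index)
        return hits

    if mode != "snv":
        raise ValueError(f"unknown mode {mode!r}")
    hits = []
    for p in table.positions:
        if p.klass not in (PositionClass.NONCPG_CONSERVED, PositionClass.NONCPG_VARIABLE):
            continue
        for j in (0, 1):
            a = {p.states[s][j] for s in partition.members_a} - {"-", "N"}
            b = {p.states[s][j] for s in partition.members_b} - {"-", "N"}
            if len(a) == 1 and len(b) == 1 and a != b:
                hits.append(p.columns[j])
    return hits


def context_counts(msa: Msa, reference_id: str, other_id: str) -> ContextCounts:
    """Per-context counts of substituted bases between two alignment rows.

    For every column where the two rows carry different bases (gap and N
    columns skipped; gaps in runs of ≥2 already carry no base), the
    reference base is tallied under the dinucleotide context formed by its
    nearest left non-gap reference neighbor and itself — into ``g_changes``
    when that base is G, else ``non_g_changes``.
    """
    ref = msa.row(reference_id)
    oth = msa.row(other_id)
    g: Counter = Counter()
    non_g: Counter = Counter()
    for col in range(msa.n_cols):
        rb, ob = ref[col], oth[col]
        if rb in "-N" or ob in "-N" or rb == ob:
            continue
        left = "N"
        for k in range(col - 1, -1, -1):
            if ref[k] != "-":
                left = ref[k]
                break
        ctx = left + rb
        (g if rb == "G" else non_g)[ctx] += 1
    return ContextCounts(g_changes=g, non_g_changes=non_g)
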