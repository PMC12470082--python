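"""Recoding CpG conservation patterns into an A/T presence/absence matrix.

Every orthologous position carrying a CpG in at least one evaluable
species becomes one character column: species whose state is CG get 'A',
species with any other evaluable state get 'T', species not evaluable at
the position get '-'. This per-species rule produces the between-species
variation a distance tree needs; a stricter column-constant variant
(conserved positions all-'A', variable positions all-'T') is available via
``rule="column"`` for exploration but is species-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .annotate import DinucPositionTable, PositionClass
from .seqio import SequenceRecord, read_fasta, write_fasta


@dataclass
class RecodedMatrix:
    ids: list[str]
    characters: list[str]          # per species, over {A,T,-}
    position_index: list[int]      # character column -> dinucleotide position index

    def __post_init__(self) -> None:
        n = len(self.characters[0]) if self.characters else 0
        if any(len(c) != n for c in self.characters):
            raise ValueError("character rows differ in length")
        if len(self.position_index) != n:
            raise ValueError("position_index length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.position_index)

    def column(self, j: int) -> str:
        return "".join(c[j] for c in self.characters)

    def to_tsv(self) -> str:
        lines = ["column\tposition_index\t" + "\t".join(self.ids)]
        for j, pidx in enumerate(self.position_index):
            lines.append(f"{j}\t{pidx}\t" + "\t".join(c[j] for c in self.characters))
        return "\n".join(lines) + "\n"


def recode_cpg(table: DinucPositionTable,
               rule: Literal["per-species", "column"] = "per-species") -> RecodedMatrix:
    """Build the A/T character matrix from a classified position table."""
    if any(p.klass is None for p in table.positions):
        raise ValueError("table must be classified first")
    cols: list[dict[str, str]] = []
    index: list[int] = []
    for p in table.positions:
        if p.klass not in (PositionClass.CONSERVED_CPG, PositionClass.VARIABLE_CPG):
            continue
        ev = p.evaluable_states()
        if rule == "per-species":
            col = {s: ("A" if ev.get(s) == "CG" else "T" if s in ev else "-")
                   for s in table.ids}
        else:
            sym = "A" if p.klass == PositionClass.CONSERVED_CPG else "T"
            col = {s: (sym if s in ev else "-") for s in table.ids}
        cols.append(col)
        index.append(p.index)
    characters = ["".join(col[s] for col in cols) for s in table.ids]
    return RecodedMatrix(ids=list(table.ids), characters=characters,
                         position_index=index)


def write_recoded_fasta(matrix: RecodedMatrix, path: str | Path) -> None:
    if matrix.n_columns == 0:
        raise ValueError(
            "recoded matrix has no CpG positions; nothing to write"
        )
    write_fasta(
        [SequenceRecord(id=s, seq=c) for s, c in zip(matrix.ids, matrix.characters)],
        path,
    )


def read_recoded_fasta(path: str | Path,
                       position_index: list[int] | None = None) -> RecodedMatrix:
    recs = read_fasta(path, allow_gaps=True)
    for r in recs:
        bad = set(r.seq) - set("AT-")
        if bad:
            raise ValueError(f"record {r.id!r}: not a recoded matrix, found {sorted(bad)}")
    n = len(recs[0].seq)
    if position_index is None:
        position_index = list(range(n))
    return RecodedMatrix(ids=[r.id for r in recs], characters=[r.seq for r in recs],
                         position_index=position_index)
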