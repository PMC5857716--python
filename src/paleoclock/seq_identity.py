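"""Pairwise percent identity of aligned protein sequences.

Identity is computed column-wise over an existing alignment: the denominator
is the number of columns where *both* sequences carry a residue (gaps '-' on
either side are excluded), and a column counts as a match only when both
residues are the same unambiguous amino-acid letter.  'X' (unknown residue)
never matches, not even another 'X'.  Input is case-insensitive and '.' is
read as a gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedPair",
    "IdentityRecord",
    "percent_identity",
    "identity_table",
    "read_aligned_fasta",
    "write_identity_tsv",
    "read_identity_tsv",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
UNKNOWN = "X"
_ALPHABET = AMINO_ACIDS | {GAP, UNKNOWN}

SUBUNIT_CHOICES = ("A-vs-A", "B-vs-B", "A-vs-B")


def _normalise(seq: str) -> str:
    seq = seq.upper().replace(".", GAP)
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-amino-acid characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class AlignedPair:
    """Two rows of an alignment, compared as a unit."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        object.__setattr__(self, "seq_a", _normalise(self.seq_a))
        object.__setattr__(self, "seq_b", _normalise(self.seq_b))
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"aligned sequences must have equal length "
                f"({len(self.seq_a)} != {len(self.seq_b)})"
            )
        if len(self.seq_a) == 0:
            raise ValueError("empty alignment")


@dataclass
class IdentityRecord:
    """One species-pair / subunit-pair identity, optionally with fossil ages."""

    pair_label: str
    subunit: str
    identity_pct: float
    divergence_age_ma: float | None = None
    age_min_ma: float | None = None
    age_max_ma: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct must lie in [0, 100]")
        if self.subunit not in SUBUNIT_CHOICES:
            raise ValueError(f"subunit must be one of {SUBUNIT_CHOICES}")
        if (
            self.age_min_ma is not None
            and self.age_max_ma is not None
            and self.age_min_ma > self.age_max_ma
        ):
            raise ValueError("age_min_ma must not exceed age_max_ma")


def percent_identity(pair: AlignedPair) -> float:
    """Percent identity over columns where both sequences are non-gap.

    Raises
    ------
    ValueError
        If no column has residues in both sequences.
    """
    matches = 0
    comparable = 0
    for a, b in zip(pair.seq_a, pair.seq_b):
        if a == GAP or b == GAP:
            continue
        comparable += 1
        if a == b and a != UNKNOWN:
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable columns: gap in one sequence at every site")
    return 100.0 * matches / comparable


def identity_table(
    pairs: list[AlignedPair],
    subunits: list[str] | None = None,
    ages: list[tuple[float | None, float | None, float | None]] | None = None,
) -> list[IdentityRecord]:
    """Build one IdentityRecord per aligned pair, preserving input order.

    ``ages`` supplies optional ``(divergence_age_ma, age_min_ma, age_max_ma)``
    per pair; ``subunits`` defaults to "A-vs-A".
    """
    records = []
    for k, pair in enumerate(pairs):
        div, lo, hi = (None, None, None) if ages is None else ages[k]
        records.append(
            IdentityRecord(
                pair_label=f"{pair.id_a} vs {pair.id_b}",
                subunit=subunits[k] if subunits is not None else "A-vs-A",
                identity_pct=percent_identity(pair),
                divergence_age_ma=div,
                age_min_ma=lo,
                age_max_ma=hi,
            )
        )
    return records


def read_aligned_fasta(path: str) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered {label: sequence} mapping.

    Sequences are uppercased; all records must share one alignment length.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seqs[rec.description] = _normalise(str(rec.seq))
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(
            f"sequences in {path} differ in length {sorted(lengths)}; "
            "input must be an alignment"
        )
    return seqs


_TSV_COLUMNS = [
    "pair_label",
    "subunit",
    "identity_pct",
    "divergence_age_ma",
    "age_min_ma",
    "age_max_ma",
]


def write_identity_tsv(records: list[IdentityRecord], path: str) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_identity_tsv(path: str) -> list[IdentityRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c) for c in _TSV_COLUMNS if hasattr(row, c)}
        for key in ("divergence_age_ma", "age_min_ma", "age_max_ma"):
            if key in d and pd.isna(d[key]):
                d[key] = None
        records.append(IdentityRecord(**d))
    return records
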