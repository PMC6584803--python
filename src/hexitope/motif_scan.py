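"""Epitope-motif conservation scanning across a protein family.

The antibody epitope on the reference isoform (human connexin 26) spans EC1
residues 54-58 (motif NTLQP) and EC2 residues 175-176 (motif PN).  For every
family member, the corresponding positions are transferred by global
pairwise alignment to the reference, the 5+2 residue motif is extracted, and
the isoform is classified: an identical motif predicts inhibition by the
antibody, any mismatch predicts weak or no inhibition.  The prediction is
deliberately binary — grading "less effective" versus "ineffective" would
require affinity modelling that is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from hexitope.errors import HexitopeError

#: reference (hCx26) epitope positions, author numbering, 1-based
EC1_POSITIONS = (54, 55, 56, 57, 58)
EC2_POSITIONS = (175, 176)

AA1 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MotifRecord:
    """The extracted 5-residue EC1 and 2-residue EC2 epitope motifs."""

    gene: str
    protein: str
    ec1_motif: str
    ec2_motif: str
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.ec1_motif) != 5 or len(self.ec2_motif) != 2:
            raise HexitopeError(
                f"{self.protein}: motif lengths must be 5 (EC1) and 2 (EC2), "
                f"got {self.ec1_motif!r}/{self.ec2_motif!r}"
            )
        bad = (set(self.ec1_motif) | set(self.ec2_motif)) - AA1
        if bad:
            raise HexitopeError(f"{self.protein}: non-standard residues {sorted(bad)}")

    @property
    def combined(self) -> str:
        return self.ec1_motif + self.ec2_motif


@dataclass
class SelectivityCall:
    isoform: str
    gene: str
    ec1_mismatches: list[tuple[int, str, str]]  # (position, reference aa, query aa)
    ec2_mismatches: list[tuple[int, str, str]]
    identical: bool
    predicted_class: str  # "inhibited" | "not_or_weakly_inhibited"
    motif: MotifRecord | None = None

    def __post_init__(self) -> None:
        n = len(self.ec1_mismatches) + len(self.ec2_mismatches)
        if self.identical != (n == 0):
            raise HexitopeError("identical flag inconsistent with mismatch lists")
        expected = "inhibited" if self.identical else "not_or_weakly_inhibited"
        if self.predicted_class != expected:
            raise HexitopeError("predicted_class inconsistent with identity")


def default_aligner(
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> PairwiseAligner:
    """Global protein aligner: BLOSUM62, gap open 10, gap extend 0.5."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def map_epitope_positions(
    query_seq: str,
    ref_seq: str,
    ref_positions: list[int] | tuple[int, ...],
    aligner: PairwiseAligner | None = None,
) -> dict[int, int | None]:
    """Transfer 1-based reference positions onto a query by global alignment.

    Returns ``{ref_position: query_position}``; a reference position aligned
    to a gap in the query maps to ``None`` (reported, never silently
    dropped).
    """
    if not query_seq or not ref_seq:
        raise HexitopeError("empty sequence")
    for p in ref_positions:
        if not 1 <= p <= len(ref_seq):
            raise HexitopeError(f"reference position {p} outside sequence (1-{len(ref_seq)})")
    if aligner is None:
        aligner = default_aligner()
    alignment = aligner.align(ref_seq, query_seq)[0]
    # column map from aligned block coordinates
    mapping: dict[int, int | None] = {p: None for p in ref_positions}
    wanted = {p - 1: p for p in ref_positions}  # 0-based -> 1-based
    ref_blocks, query_blocks = alignment.aligned
    for (r0, r1), (q0, q1) in zip(ref_blocks, query_blocks):
        for off in range(r1 - r0):
            ri = r0 + off
            if ri in wanted:
                mapping[wanted[ri]] = q0 + off + 1  # back to 1-based
    return mapping


def extract_motif(
    seq: str,
    positions: dict[int, int | None],
    gene: str = "",
    protein: str = "",
) -> MotifRecord:
    """Concatenate query residues at the mapped EC1/EC2 positions."""
    unmapped = [p for p in (*EC1_POSITIONS, *EC2_POSITIONS) if positions.get(p) is None]
    if unmapped:
        raise HexitopeError(
            f"{protein or 'query'}: epitope position(s) {unmapped} unalignable"
        )
    ec1 = "".join(seq[positions[p] - 1] for p in EC1_POSITIONS)
    ec2 = "".join(seq[positions[p] - 1] for p in EC2_POSITIONS)
    return MotifRecord(gene=gene, protein=protein, ec1_motif=ec1, ec2_motif=ec2)


def classify_selectivity(motif: MotifRecord, reference: MotifRecord) -> SelectivityCall:
    """Position-wise comparison of the 7 motif residues against the reference."""
    ec1_mm = [
        (pos, r, q)
        for pos, r, q in zip(EC1_POSITIONS, reference.ec1_motif, motif.ec1_motif)
        if r != q
    ]
    ec2_mm = [
        (pos, r, q)
        for pos, r, q in zip(EC2_POSITIONS, reference.ec2_motif, motif.ec2_motif)
        if r != q
    ]
    identical = not ec1_mm and not ec2_mm
    return SelectivityCall(
        isoform=motif.protein,
        gene=motif.gene,
        ec1_mismatches=ec1_mm,
        ec2_mismatches=ec2_mm,
        identical=identical,
        predicted_class="inhibited" if identical else "not_or_weakly_inhibited",
        motif=motif,
    )


def _parse_header(record) -> tuple[str, str]:
    """FASTA id convention: ``>PROTEIN gene=GENE ...`` or ``>GENE|PROTEIN``."""
    rid = record.id
    if "|" in rid:
        gene, protein = rid.split("|", 1)
    else:
        protein, gene = rid, ""
        for token in record.description.split():
            if token.startswith("gene="):
                gene = token[5:]
    return gene, protein


def scan_family(
    fasta_path: str,
    ref_seq: str,
    ref_record: MotifRecord,
    aligner: PairwiseAligner | None = None,
) -> list[SelectivityCall]:
    """Classify every sequence in a FASTA against the reference motif.

    Input order is preserved; duplicate sequence identifiers are an error.
    """
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if not records:
        raise HexitopeError(f"{fasta_path}: no sequences")
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise HexitopeError(f"{fasta_path}: duplicate sequence identifiers")
    if aligner is None:
        aligner = default_aligner()
    calls = []
    for record in records:
        gene, protein = _parse_header(record)
        seq = str(record.seq)
        positions = map_epitope_positions(
            seq, ref_seq, [*EC1_POSITIONS, *EC2_POSITIONS], aligner
        )
        motif = extract_motif(seq, positions, gene=gene, protein=protein)
        calls.append(classify_selectivity(motif, ref_record))
    return calls


def calls_to_frame(calls: list[SelectivityCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene": c.gene,
                "protein": c.isoform,
                "ec1_motif": c.motif.ec1_motif if c.motif else "",
                "ec2_motif": c.motif.ec2_motif if c.motif else "",
                "n_mismatches": len(c.ec1_mismatches) + len(c.ec2_mismatches),
                "mismatches": ";".join(
                    f"{r}{p}{q}" for p, r, q in (*c.ec1_mismatches, *c.ec2_mismatches)
                ),
                "identical": c.identical,
                "predicted_class": c.predicted_class,
            }
        )
    return pd.DataFrame(rows)
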