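"""Sequence-level screens for DRE/CRT cis-elements and AP2 domains.

The dehydration-responsive element (DRE/CRT) carries the core motif
[A/G]CCGAC; stress-responsive AP2/ERF transcription factors of the DREB
family bind it and are recognized by carrying exactly one ~60-residue AP2
DNA-binding domain. This module provides the building blocks of that
screen: ORF translation, iterated Smith–Waterman domain search with a
single-domain filter, strand-aware promoter extraction, IUPAC motif
scanning on both strands, and tandem-repeat bait construction for
yeast-one-hybrid vectors.

Coordinates are 0-based half-open internally; file interfaces that take
or emit gene coordinates use 1-based inclusive positions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "MotifHit",
    "DomainHit",
    "DRE_ELEMENTS",
    "translate_cds",
    "scan_dre",
    "find_domains",
    "single_domain_filter",
    "extract_promoters",
    "build_tandem",
    "default_ap2_consensus",
]

#: Named DRE elements: the [A/G]CCGAC core plus the three yeast-one-hybrid
#: bait 9-mers and the non-binding mutant control.
DRE_ELEMENTS: dict[str, str] = {
    "core": "RCCGAC",
    "DRE1": "GACCGACGA",
    "DRE2": "AGCCGACAC",
    "DRE3": "CGCCGACTT",
    "mDRE": "TATTTTCAT",
}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifHit:
    """A located motif match, in forward-strand coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    matched_text: str
    element_name: str


@dataclass(frozen=True)
class DomainHit:
    """A local-alignment domain hit on a protein (residue coordinates)."""

    prot_id: str
    start: int
    end: int
    score: float
    identity: float


def translate_cds(seq, seq_id: str = "", table: int = 1) -> str:
    """Translate a CDS; the terminal stop codon is dropped.

    The sequence length must be a multiple of 3; a non-ATG start only
    warns. An internal stop raises with the offending codon position.
    A 579-nt CDS ending in a stop codon therefore yields 192 residues.
    """
    s = str(seq).upper()
    if len(s) == 0 or len(s) % 3 != 0:
        raise ValueError("CDS length must be a positive multiple of 3")
    if not s.startswith("ATG"):
        warnings.warn(f"CDS {seq_id or '<anon>'} does not start with ATG", stacklevel=2)
    prot = str(Seq(s).translate(table=table))
    internal = prot[:-1].find("*")
    if internal != -1:
        raise ValueError(
            f"internal stop codon at codon {internal + 1} "
            f"(nt {3 * internal + 1}-{3 * internal + 3})"
        )
    return prot[:-1] if prot.endswith("*") else prot


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC nucleotide code: {ch!r}")
        exp = _IUPAC[ch]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_dre(
    seq,
    seq_id: str = "",
    elements: dict[str, str] | None = None,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All (possibly overlapping) element matches, both strands.

    Reverse-strand matches are found by searching the reverse-complement
    pattern on the forward strand, so coordinates always refer to the
    forward strand. Hits are sorted by (start, end, strand, element).
    """
    s = str(seq).upper()
    elements = DRE_ELEMENTS if elements is None else elements
    hits: list[MotifHit] = []
    for name, pattern in elements.items():
        for strand in ("+", "-") if both_strands else ("+",):
            pat = pattern if strand == "+" else reverse_complement(pattern)
            rx = _pattern_regex(pat)
            for m in rx.finditer(s):
                start, text = m.start(1), m.group(1)
                hits.append(
                    MotifHit(seq_id, start, start + len(text), strand, text, name)
                )
    hits.sort(key=lambda h: (h.start, h.end, h.strand, h.element_name))
    return hits


def _make_aligner(gap_open: float, gap_extend: float, matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def find_domains(
    prot,
    consensus,
    prot_id: str = "",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    min_score: float = 80.0,
    matrix: str = "BLOSUM62",
) -> list[DomainHit]:
    """Iterated Smith–Waterman search for domain copies in a protein.

    The best local alignment of ``consensus`` against the protein is
    reported as a hit, its region masked out, and the search repeated
    until the best score drops below ``min_score``. Hits are therefore
    non-overlapping; they are returned sorted by position.
    """
    target = str(prot).upper()
    query = str(consensus).upper()
    if not target or not query:
        raise ValueError("empty sequence")
    if min_score <= 0:
        raise ValueError("min_score must be positive")
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    hits: list[DomainHit] = []
    masked = target
    while True:
        alignments = aligner.align(masked, query)
        if len(alignments) == 0:
            break
        best = alignments[0]
        if best.score < min_score:
            break
        blocks = best.aligned[0]
        start, end = int(blocks[0][0]), int(blocks[-1][1])
        matched = 0
        total = 0
        for (ts, te), (qs, qe) in zip(best.aligned[0], best.aligned[1]):
            for t_i, q_i in zip(range(ts, te), range(qs, qe)):
                total += 1
                if masked[t_i] == query[q_i]:
                    matched += 1
        hits.append(
            DomainHit(prot_id, start, end, float(best.score), matched / max(total, 1))
        )
        masked = masked[:start] + "X" * (end - start) + masked[end:]
    hits.sort(key=lambda h: h.start)
    return hits


def single_domain_filter(proteins: dict[str, str], consensus, **params) -> list[str]:
    """Ids of proteins carrying exactly one domain hit."""
    return [
        pid
        for pid, seq in proteins.items()
        if len(find_domains(seq, consensus, prot_id=pid, **params)) == 1
    ]


def extract_promoters(
    genome: dict[str, str],
    genes: pd.DataFrame,
    upstream_bp: int = 2000,
) -> dict[str, str]:
    """Upstream promoter sequences, 5'->3' toward each gene.

    ``genes`` has columns seqid, start, end, strand, gene_id with 1-based
    inclusive coordinates. For '+' genes the ``upstream_bp`` bases before
    ``start`` are returned; for '-' genes the bases after ``end``,
    reverse-complemented. Windows are truncated (with a warning) at
    contig edges.
    """
    out: dict[str, str] = {}
    for row in genes.itertuples(index=False):
        if row.seqid not in genome:
            raise KeyError(f"unknown contig {row.seqid!r}")
        contig = str(genome[row.seqid]).upper()
        if row.strand == "+":
            end0 = int(row.start) - 1  # 0-based exclusive end of the window
            start0 = max(0, end0 - upstream_bp)
            prom = contig[start0:end0]
        elif row.strand == "-":
            start0 = int(row.end)  # 0-based inclusive start of the window
            end0 = min(len(contig), start0 + upstream_bp)
            prom = reverse_complement(contig[start0:end0])
        else:
            raise ValueError(f"invalid strand {row.strand!r} for {row.gene_id}")
        if len(prom) < upstream_bp:
            warnings.warn(
                f"promoter of {row.gene_id} truncated to {len(prom)} bp at contig edge",
                stacklevel=2,
            )
        out[row.gene_id] = prom
    return out


def default_ap2_consensus() -> str:
    """The packaged AP2-domain-like consensus sequence.

    A synthetic ~60-residue stand-in with the character of an AP2/ERF
    DNA-binding domain, shipped so the single-domain filter runs without
    any external profile database.
    """
    from importlib.resources import files

    text = files("heatscreen").joinpath("data/ap2_consensus.synthetic.fa").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


def build_tandem(element, n: int = 3, spacer: str = "") -> str:
    """Concatenate ``n`` copies of an element, joined by ``spacer``."""
    if n < 1:
        raise ValueError("need n >= 1")
    return spacer.join([str(element).upper()] * n)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: sequence} preserving order."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
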