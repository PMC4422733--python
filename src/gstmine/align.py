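"""Pairwise protein alignment, conservation line, identity/similarity metrics.

Global (Needleman-Wunsch) and local (Smith-Waterman) alignment are delegated
to Biopython's ``PairwiseAligner`` with a BLOSUM62 / affine-gap
parameterisation (a gap of length *k* costs ``open + (k-1) * extend``,
applied to end gaps too in global mode).

The metrics follow the convention used throughout this package's reports:

* percent identity = identical residue pairs / residues of the *longest*
  sequence (ungapped count) x 100;
* percent similarity adds pairs falling in the same Clustal strong (":")
  or weak (".") conservation group;
* for partial proteins the computation is restricted to the region of
  overlap — the closed column interval where both rows have residues — and
  the denominator is the larger ungapped residue count within that span.

``X`` never counts as identical or similar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .records import AA_ALPHABET

#: Clustal conservation groups (as used for ":" and "." in alignment output).
STRONG_GROUPS = ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
WEAK_GROUPS = ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
               "NDEQHK", "NEQHRK", "FVLIM", "HFY")

_STRONG_SETS = tuple(frozenset(g) for g in STRONG_GROUPS)
_WEAK_SETS = tuple(frozenset(g) for g in WEAK_GROUPS)


def same_strong_group(a: str, b: str) -> bool:
    return any(a in g and b in g for g in _STRONG_SETS)


def same_weak_group(a: str, b: str) -> bool:
    return any(a in g and b in g for g in _WEAK_SETS)


@dataclass(frozen=True)
class AlignerConfig:
    """Substitution matrix and affine gap penalties (BLAST-like defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def make(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        aligner.mode = mode
        return aligner


DEFAULT_CONFIG = AlignerConfig()


@dataclass
class AlignmentResult:
    """Two aligned rows, a conservation line and the alignment score."""

    row_a: str
    row_b: str
    conservation: str
    score: float
    mode: str

    def __post_init__(self) -> None:
        if not (len(self.row_a) == len(self.row_b) == len(self.conservation)):
            raise ValueError("alignment rows and conservation line differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    def format_clustal(self, name_a: str = "seq_a", name_b: str = "seq_b",
                       width: int = 60) -> str:
        """Clustal-style 3-row block text."""
        pad = max(len(name_a), len(name_b)) + 2
        lines = []
        for i in range(0, self.n_columns, width):
            lines.append(f"{name_a:<{pad}}{self.row_a[i:i+width]}")
            lines.append(f"{name_b:<{pad}}{self.row_b[i:i+width]}")
            lines.append(f"{'':<{pad}}{self.conservation[i:i+width]}")
            lines.append("")
        return "\n".join(lines)


@dataclass
class IdentityReport:
    pct_identity: float
    pct_similarity: float
    n_identical: int
    n_similar: int
    denominator: int
    overlap_used: bool
    overlap_span: Optional[tuple[int, int]] = None  # 1-based column interval

    def rounded(self) -> tuple[int, int]:
        """Integer percentages as printed in report tables."""
        return round(self.pct_identity), round(self.pct_similarity)


def conservation_line(row_a: str, row_b: str) -> str:
    """Clustal symbols per column: '*' identical, ':' strong, '.' weak.

    Gaps, 'X' and stop characters never produce a symbol.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    out = []
    for a, b in zip(row_a, row_b):
        if a in AA_ALPHABET and b in AA_ALPHABET:
            if a == b:
                out.append("*")
            elif same_strong_group(a, b):
                out.append(":")
            elif same_weak_group(a, b):
                out.append(".")
            else:
                out.append(" ")
        else:
            out.append(" ")
    return "".join(out)


def _validate(seq: str, allow_stops: bool) -> None:
    allowed = AA_ALPHABET | {"X"}
    if allow_stops:
        allowed = allowed | {"*"}
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-amino-acid character(s) {sorted(bad)} in sequence")
    if not seq:
        raise ValueError("empty sequence")


def align(a: str, b: str, mode: str = "global",
          config: AlignerConfig = DEFAULT_CONFIG,
          allow_stops: bool = False) -> AlignmentResult:
    """Optimal pairwise alignment of two protein sequences.

    ``mode`` is ``"global"`` (Needleman-Wunsch, end gaps penalised) or
    ``"local"`` (Smith-Waterman).  ``allow_stops`` permits '*' characters,
    needed when aligning against raw frame translations.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    _validate(a, allow_stops)
    _validate(b, allow_stops)
    aligner = config.make(mode)
    alignments = aligner.align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        # local mode with no positive-scoring pair: the empty alignment
        return AlignmentResult("", "", "", 0.0, mode)
    row_a, row_b = str(best[0]), str(best[1])
    return AlignmentResult(row_a, row_b, conservation_line(row_a, row_b),
                           float(best.score), mode)


def score(a: str, b: str, mode: str = "local",
          config: AlignerConfig = DEFAULT_CONFIG) -> float:
    """Alignment score only (faster than building the full alignment)."""
    return float(config.make(mode).score(a, b))


def _ungapped(row: str) -> int:
    return sum(1 for c in row if c != "-")


def identity_report(aln: AlignmentResult, partial_mode: bool = False) -> IdentityReport:
    """Identity/similarity percentages from an alignment.

    With ``partial_mode`` the counts and the longest-sequence denominator are
    restricted to the region of overlap (first through last column where both
    rows are non-gap).
    """
    row_a, row_b, cons = aln.row_a, aln.row_b, aln.conservation
    span: Optional[tuple[int, int]] = None
    if partial_mode:
        both = [i for i, (x, y) in enumerate(zip(row_a, row_b))
                if x != "-" and y != "-"]
        if not both:
            raise ValueError("no overlap between the two aligned sequences")
        lo, hi = both[0], both[-1] + 1
        span = (lo + 1, hi)  # 1-based inclusive columns
        row_a, row_b, cons = row_a[lo:hi], row_b[lo:hi], cons[lo:hi]
    denominator = max(_ungapped(row_a), _ungapped(row_b))
    n_identical = cons.count("*")
    n_similar = cons.count(":") + cons.count(".")
    return IdentityReport(
        pct_identity=100.0 * n_identical / denominator,
        pct_similarity=100.0 * (n_identical + n_similar) / denominator,
        n_identical=n_identical,
        n_similar=n_similar,
        denominator=denominator,
        overlap_used=partial_mode,
        overlap_span=span,
    )


def pairwise_identity(a: str, b: str, partial_mode: bool = False,
                      config: AlignerConfig = DEFAULT_CONFIG) -> IdentityReport:
    """Global alignment of two sequences and its identity report.

    The pair is aligned in a canonical orientation so the metrics are exactly
    symmetric in their arguments (co-optimal alignment paths might otherwise
    be tie-broken differently depending on argument order).
    """
    if b < a:
        aln = align(b, a, "global", config)
        aln = AlignmentResult(aln.row_b, aln.row_a, aln.conservation,
                              aln.score, aln.mode)
    else:
        aln = align(a, b, "global", config)
    return identity_report(aln, partial_mode=partial_mode)
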