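"""Domain-presence vetting by PSSM scoring, and wildcard motif scanning.

Domain presence (GSTN, GSTC, THX, MAPEG) is decided by sliding a log-odds
position-specific scoring matrix — built from a shipped seed alignment —
along the protein and comparing the best mean per-column score against a
per-domain threshold calibrated on shuffled-protein nulls.  Partial overlaps
down to ``min_cols`` columns are scored, so a truncated protein can still
present the surviving domain.

Motif scanning handles PROSITE-style fixed/wildcard patterns (wildcard
character ``x``, case-insensitive) and reports every window within the
mismatch budget together with its substitution list; substitutions are
classified conservative when the expected and observed residues share a
Clustal strong or weak group.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .align import same_strong_group, same_weak_group
from .orf import Completeness, DeducedProtein
from .records import read_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

DOMAIN_NAMES = ("GSTN", "GSTC", "THX", "MAPEG")

#: conserved 16-mer diagnostic of microsomal GST-1 proteins; positions 7, 12
#: and 16 are variable.
MGST1_MOTIF = "VERVRRxHLNDxENIx"

DEFAULT_MIN_COLS = 50


@dataclass
class DomainCall:
    domain_name: str
    start: int            # 1-based inclusive protein positions
    end: int
    score: float          # mean per-column log-odds (bits) of the best window
    present: bool

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid domain span")


@dataclass
class Substitution:
    motif_position: int   # 1-based within the pattern
    expected: str
    observed: str
    conservative: bool


@dataclass
class MotifMatch:
    pattern: str
    start: int            # 1-based protein position of the window
    n_mismatches: int
    substitutions: list[Substitution]


class Pssm:
    """Log-odds position-specific scoring matrix from an ungapped-column MSA."""

    def __init__(self, name: str, matrix: np.ndarray):
        self.name = name
        self.matrix = matrix  # (length, 20) bits vs uniform background

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_seed(cls, name: str, sequences: Sequence[str],
                  pseudocount: float = 0.5) -> "Pssm":
        rows = [s.upper() for s in sequences]
        length = len(rows[0])
        if any(len(r) != length for r in rows):
            raise ValueError(f"seed alignment {name!r}: rows differ in length")
        counts = np.full((length, 20), pseudocount)
        for r in rows:
            for j, c in enumerate(r):
                if c in _AA_INDEX:
                    counts[j, _AA_INDEX[c]] += 1.0
        freqs = counts / counts.sum(axis=1, keepdims=True)
        background = 1.0 / 20.0
        return cls(name, np.log2(freqs / background))

    def _encode(self, seq: str) -> np.ndarray:
        return np.array([_AA_INDEX.get(c, -1) for c in seq])

    def best_window(self, seq: str, min_cols: int = DEFAULT_MIN_COLS
                    ) -> tuple[float, int, int]:
        """Best mean per-column score and its protein span (1-based).

        All contiguous pssm-column/protein offsets with at least
        ``min(min_cols, len(seq), len(self))`` overlapping columns are scored;
        unknown residues (X) contribute 0.
        """
        L, n = len(self), len(seq)
        idx = self._encode(seq)
        wmin = min(min_cols, n, L)
        best = (-np.inf, 1, min(n, 1))
        # offset o aligns pssm column j to protein position j + o (0-based)
        for o in range(-(L - wmin), n - wmin + 1):
            j0 = max(0, -o)
            j1 = min(L, n - o)
            if j1 - j0 < wmin:
                continue
            cols = np.arange(j0, j1)
            res = idx[cols + o]
            valid = res >= 0
            total = float(self.matrix[cols[valid], res[valid]].sum())
            mean = total / (j1 - j0)
            if mean > best[0]:
                best = (mean, j0 + o + 1, j1 - 1 + o + 1)
        return best


@dataclass
class ProfileSet:
    """Domain PSSMs plus their presence thresholds (bits per column)."""

    pssms: dict[str, Pssm]
    thresholds: dict[str, float]
    min_cols: int = DEFAULT_MIN_COLS

    def __post_init__(self) -> None:
        missing = [d for d in self.pssms if d not in self.thresholds]
        if missing:
            raise ValueError(f"no threshold for domain(s) {missing}")

    def require(self, domains: Iterable[str]) -> None:
        missing = [d for d in domains if d not in self.pssms]
        if missing:
            raise ValueError(f"profile set is missing required domain(s) {missing}")


def load_profiles(directory: str | Path | None = None) -> ProfileSet:
    """Load seed alignments and thresholds from a profile directory.

    The directory holds one aligned FASTA per domain (``<name>.synthetic_seed.fasta``,
    lower-case name) and a ``thresholds.yaml``; the default is the package's
    built-in synthetic seed set.
    """
    if directory is None:
        directory = importlib.resources.files("gstmine") / "data" / "profiles"
    directory = Path(str(directory))
    with open(directory / "thresholds.yaml") as fh:
        meta = yaml.safe_load(fh)
    thresholds = {k.upper(): float(v) for k, v in meta["thresholds"].items()}
    min_cols = int(meta.get("min_cols", DEFAULT_MIN_COLS))
    pssms = {}
    for name in DOMAIN_NAMES:
        seed_path = directory / f"{name.lower()}.synthetic_seed.fasta"
        if not seed_path.exists():
            continue
        seqs = [r.seq for r in read_fasta(seed_path, kind="protein")]
        pssms[name] = Pssm.from_seed(name, seqs)
    return ProfileSet(pssms=pssms, thresholds=thresholds, min_cols=min_cols)


def consensus_sequence(directory: str | Path | None, name: str) -> str:
    """First (consensus) row of a domain's seed alignment."""
    if directory is None:
        directory = importlib.resources.files("gstmine") / "data" / "profiles"
    recs = read_fasta(Path(str(directory)) / f"{name.lower()}.synthetic_seed.fasta",
                      kind="protein")
    return recs[0].seq


def scan_domains(protein: DeducedProtein | str, profiles: ProfileSet,
                 domains: Iterable[str] = DOMAIN_NAMES) -> list[DomainCall]:
    """Best-scoring window per domain, flagged present by threshold."""
    seq = protein.aa_seq if isinstance(protein, DeducedProtein) else protein
    profiles.require(domains)
    calls = []
    for name in domains:
        pssm = profiles.pssms[name]
        mean, start, end = pssm.best_window(seq, profiles.min_cols)
        calls.append(DomainCall(name, start, end, mean,
                                present=mean >= profiles.thresholds[name]))
    return calls


#: structural domains expected per class (full-length proteins)
EXPECTED_DOMAINS = {
    "cytosolic": ("GSTN", "GSTC"),
    "mitochondrial": ("THX",),
    "microsomal": ("MAPEG",),
}


def expected_complement_ok(gst_class: str, completeness: Completeness,
                           calls: Sequence[DomainCall]) -> bool:
    """Does the protein carry the domain complement expected for its class?

    Full-length proteins must present every expected domain; partials may
    lack the domain(s) at their missing terminus, so any one expected domain
    suffices.
    """
    expected = EXPECTED_DOMAINS.get(gst_class)
    if expected is None:
        return False
    present = {c.domain_name for c in calls if c.present}
    if completeness in (Completeness.FULL_LENGTH, Completeness.PUTATIVE_FULL_LENGTH):
        return all(d in present for d in expected)
    return any(d in present for d in expected)


def scan_motif(seq: str, pattern: str = MGST1_MOTIF,
               max_mismatches: int = 0) -> list[MotifMatch]:
    """All windows matching a fixed/wildcard pattern within a mismatch budget.

    Wildcard positions (``x``) match anything and never produce
    substitutions.  Each reported substitution carries its 1-based motif
    position, the expected (pattern) and observed residues, and a
    conservative/non-conservative classification.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    if isinstance(seq, DeducedProtein):
        seq = seq.aa_seq
    seq = seq.upper()
    k = len(pattern)
    fixed = [(i, c.upper()) for i, c in enumerate(pattern) if c not in ("x", "X")]
    matches = []
    for start in range(len(seq) - k + 1):
        window = seq[start:start + k]
        subs = []
        for i, expected in fixed:
            observed = window[i]
            if observed != expected:
                subs.append(Substitution(
                    motif_position=i + 1,
                    expected=expected,
                    observed=observed,
                    conservative=(same_strong_group(expected, observed)
                                  or same_weak_group(expected, observed)),
                ))
        if len(subs) <= max_mismatches:
            matches.append(MotifMatch(pattern=pattern, start=start + 1,
                                      n_mismatches=len(subs), substitutions=subs))
    return matches
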