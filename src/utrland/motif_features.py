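"""Sequence-level 5' end and 5'UTR feature extraction.

Classifies 5' terminal oligopyrimidine (TOP) status, scans for
pyrimidine-rich translational elements (PRTEs), counts NUG/uORF start
sites, and computes GC content and a base-pairing folding proxy for
5'UTR sequences.

Sequences are DNA/RNA strings over ``{A, C, G, T, U, N}``; T and U are
treated as equivalent and case is ignored.  ``N`` never counts as a
pyrimidine, never matches any motif and breaks pyrimidine runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

__all__ = [
    "TopStatus",
    "MotifHit",
    "UtrFeatureVector",
    "normalize_sequence",
    "pyrimidine_run_length",
    "classify_top_status",
    "scan_prte",
    "nug_sites",
    "count_uorfs_strict",
    "gc_content",
    "fold_proxy",
    "utr_features",
]

#: Pyrimidine bases after normalization (U is mapped to T).
PYRIMIDINES = frozenset("CT")

#: uORF start trinucleotides (NUG codons), DNA alphabet.
NUG_CODONS = frozenset({"ATG", "CTG", "GTG", "TTG"})

#: Stop trinucleotides, DNA alphabet.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

PRTE_LENGTH = 9
#: 0-based index of the invariant U/T within the 9-mer (position 6, 1-based).
PRTE_INVARIANT_INDEX = 5

_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(seq: str) -> str:
    """Uppercase a sequence and map U to T.

    Raises ``ValueError`` on characters outside ``{A, C, G, T, U, N}``.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of a normalized DNA sequence."""
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TopStatus:
    """TOP classification of a transcript 5' end.

    ``label`` is one of ``TOP``, ``TOP_LIKE`` or ``NON_TOP``;
    ``run_length`` is the pyrimidine run length starting at +1
    (including the +1 base), capped.
    """

    label: str
    run_length: int

    @property
    def is_top(self) -> bool:
        return self.label == "TOP"


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence at a 0-based ``offset`` within a scanned sequence."""

    offset: int
    kind: str  # "PRTE" or "NUG"
    matched: str


@dataclass(frozen=True)
class UtrFeatureVector:
    """Per-5'UTR feature bundle."""

    length: int
    gc: float
    nug_count: int
    nug_density: float
    uorf_strict_count: int
    mfe_proxy: float
    mfe_per_nt: float
    mfe_engine: str = "pairing_proxy"


def pyrimidine_run_length(seq: str, start: int = 0, cap: int = 16) -> int:
    """Length of the maximal contiguous C/U run beginning exactly at ``start``.

    Returns 0 if the base at ``start`` is a purine or N; the run length is
    truncated at ``cap``.
    """
    s = normalize_sequence(seq)
    if not 0 <= start < len(s):
        raise IndexError(f"start {start} out of range for sequence of length {len(s)}")
    run = 0
    for base in s[start:]:
        if base not in PYRIMIDINES:
            break
        run += 1
        if run >= cap:
            return cap
    return run


def classify_top_status(five_prime_seq: str, cap: int = 16) -> TopStatus:
    """Classify a transcript 5' end as TOP, TOP-like or non-TOP.

    TOP: a C at the +1 position followed by >=4 contiguous pyrimidines.
    TOP-like: a C at +1 followed by 1-3 pyrimidines, or a U at +1
    followed by >=4 pyrimidines.  Everything else is NON_TOP.

    Pyrimidine runs longer than ``cap`` still qualify; ``cap`` only
    truncates the reported ``run_length``.
    """
    s = normalize_sequence(five_prime_seq)
    if not s:
        raise ValueError("cannot classify an empty sequence")
    run = pyrimidine_run_length(s, 0, cap=cap)
    first = s[0]
    following = run - 1  # pyrimidines after the +1 base (capped)
    if first == "C" and following >= 4:
        label = "TOP"
    elif first == "C" and 1 <= following <= 3:
        label = "TOP_LIKE"
    elif first == "T" and following >= 4:
        label = "TOP_LIKE"
    else:
        label = "NON_TOP"
    return TopStatus(label=label, run_length=run)


def scan_prte(seq: str) -> list[MotifHit]:
    """All PRTE hits: 9 contiguous pyrimidines with U/T at the 6th position.

    Overlapping hits are all reported.  Sequences shorter than 9 nt yield
    an empty list.
    """
    s = normalize_sequence(seq)
    hits: list[MotifHit] = []
    for i in range(len(s) - PRTE_LENGTH + 1):
        window = s[i : i + PRTE_LENGTH]
        if window[PRTE_INVARIANT_INDEX] != "T":
            continue
        if all(b in PYRIMIDINES for b in window):
            hits.append(MotifHit(offset=i, kind="PRTE", matched=window))
    return hits


def has_prte(seq: str) -> bool:
    """True if the sequence contains at least one PRTE 9-mer."""
    s = normalize_sequence(seq)
    for i in range(len(s) - PRTE_LENGTH + 1):
        if s[i + PRTE_INVARIANT_INDEX] != "T":
            continue
        if all(b in PYRIMIDINES for b in s[i : i + PRTE_LENGTH]):
            return True
    return False


def nug_sites(utr: str) -> list[MotifHit]:
    """All 0-based offsets of NUG codons (AUG/CUG/GUG/UUG) in the UTR."""
    s = normalize_sequence(utr)
    return [
        MotifHit(offset=i, kind="NUG", matched=s[i : i + 3])
        for i in range(len(s) - 2)
        if s[i : i + 3] in NUG_CODONS
    ]


def count_uorfs_strict(utr: str) -> int:
    """NUG starts with an in-frame stop codon fully inside the UTR.

    The stop must lie strictly downstream of the start codon.
    """
    s = normalize_sequence(utr)
    n = 0
    for hit in nug_sites(s):
        for j in range(hit.offset + 3, len(s) - 2, 3):
            if s[j : j + 3] in STOP_CODONS:
                n += 1
                break
    return n


def gc_content(seq: str) -> float:
    """(G + C) / length; N counts in the denominator only."""
    s = normalize_sequence(seq)
    if not s:
        raise ValueError("cannot compute GC content of an empty sequence")
    return (s.count("G") + s.count("C")) / len(s)


#: Watson-Crick plus G.U wobble pairs (DNA alphabet, so U == T).
_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")})


def fold_proxy(
    seq: str,
    min_loop: int = 3,
    engine: Optional[Callable[[str], float]] = None,
) -> float:
    """Pseudo-energy of a 5'UTR: -1 per base pair in the maximum nested pairing.

    Dynamic programming over subsequences (Nussinov-style), counting
    Watson-Crick and G.U pairs, with hairpin loops of at least
    ``min_loop`` unpaired bases.  When an ``engine`` callable is
    supplied, its reported minimum free energy is returned instead.
    """
    s = normalize_sequence(seq)
    if not s:
        raise ValueError("cannot fold an empty sequence")
    if engine is not None:
        return float(engine(seq))
    n = len(s)
    if n <= min_loop + 1:
        return 0.0
    # dp[i][j]: max pairs in s[i..j]
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                paired = ((s[k], s[j]) in _PAIRS)
                if not paired:
                    continue
                left = dp[i][k - 1] if k > i else 0
                inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                cand = left + inner + 1
                if cand > best:
                    best = cand
            dp[i][j] = best
    return -float(dp[0][n - 1])


def utr_features(
    utr: str,
    min_loop: int = 3,
    engine: Optional[Callable[[str], float]] = None,
) -> UtrFeatureVector:
    """Assemble the full feature vector for one 5'UTR."""
    s = normalize_sequence(utr)
    if not s:
        raise ValueError("cannot featurize an empty sequence")
    nugs = nug_sites(s)
    mfe = fold_proxy(s, min_loop=min_loop, engine=engine)
    return UtrFeatureVector(
        length=len(s),
        gc=gc_content(s),
        nug_count=len(nugs),
        nug_density=len(nugs) / len(s),
        uorf_strict_count=count_uorfs_strict(s),
        mfe_proxy=mfe,
        mfe_per_nt=mfe / len(s),
        mfe_engine="external" if engine is not None else "pairing_proxy",
    )
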