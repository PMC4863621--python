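"""Canonical k-mer composition profiling.

A k-mer is *canonical* when it is lexicographically <= its reverse complement;
folding every window onto its canonical form makes profiles strand-independent
(for k=4 there are 136 canonical tetranucleotides). Profiles are frequency
vectors over the canonical index and are the genomic signature used for
composition-based bin-membership testing and for the self-organizing map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Sequence

import numpy as np

from .seqio import ScaffoldRecord

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
# Base encoding for vectorized counting; N (and anything else) -> -1.
_ENC = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@lru_cache(maxsize=None)
def canonical_kmer_index(k: int) -> tuple[str, ...]:
    """Ordered (lexicographic) tuple of canonical k-mers for 1 <= k <= 8."""
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    canon = sorted(
        {min(kmer, revcomp(kmer)) for kmer in map("".join, product(_BASES, repeat=k))}
    )
    return tuple(canon)


@lru_cache(maxsize=None)
def _fold_table(k: int) -> np.ndarray:
    """Map each of the 4^k integer-encoded k-mers to its canonical column."""
    canon = canonical_kmer_index(k)
    col = {kmer: i for i, kmer in enumerate(canon)}
    table = np.empty(4**k, dtype=np.int64)
    for code, kmer in enumerate(map("".join, product(_BASES, repeat=k))):
        table[code] = col[min(kmer, revcomp(kmer))]
    return table


@dataclass
class KmerProfile:
    """Canonical k-mer counts and frequencies of one sequence."""

    k: int
    counts: np.ndarray
    n_windows: int
    canonical: bool = True

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.n_windows


def profile_sequence(sequence: str, k: int = 4) -> KmerProfile:
    """Count canonical k-mers over all sliding windows; windows containing N
    are skipped and do not enter ``n_windows``."""
    if len(sequence) < k:
        raise ValueError("no countable windows: sequence shorter than k")
    enc = _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n_win = len(sequence) - k + 1
    codes = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        b = enc[j : j + n_win]
        valid &= b >= 0
        codes = codes * 4 + np.where(b >= 0, b, 0)
    codes = codes[valid]
    if codes.size == 0:
        raise ValueError("no countable windows: every window contains N")
    counts = np.bincount(_fold_table(k)[codes], minlength=len(canonical_kmer_index(k)))
    return KmerProfile(k=k, counts=counts, n_windows=int(codes.size))


@dataclass
class Fragment:
    fragment_id: str
    scaffold_id: str
    start_bp: int
    end_bp: int
    freqs: np.ndarray


@dataclass
class FragmentSet:
    """Fixed-size scaffold fragments with their composition feature vectors
    (the inputs to ESOM training)."""

    fragments: list[Fragment]
    window_bp: int
    min_fragment_bp: int
    k: int

    def feature_matrix(self) -> np.ndarray:
        return np.vstack([f.freqs for f in self.fragments])

    def fragment_ids(self) -> list[str]:
        return [f.fragment_id for f in self.fragments]


def fragment_scaffolds(
    records: Sequence[ScaffoldRecord],
    window_bp: int = 5000,
    min_fragment_bp: int = 2500,
    k: int = 4,
) -> FragmentSet:
    """Cut scaffolds into consecutive windows and profile each fragment.

    The terminal remainder is kept iff >= ``min_fragment_bp``; scaffolds
    shorter than ``min_fragment_bp`` are skipped with a warning.
    """
    if not records:
        raise ValueError("fragment_scaffolds: no records")
    fragments: list[Fragment] = []
    for rec in records:
        L = len(rec)
        if L < min_fragment_bp:
            logger.warning(
                "scaffold %s (%d bp) shorter than min fragment %d bp; skipped",
                rec.scaffold_id,
                L,
                min_fragment_bp,
            )
            continue
        cuts = list(range(0, L, window_bp))
        ordinal = 0
        for start in cuts:
            end = min(start + window_bp, L)
            if end - start < min_fragment_bp:
                break
            try:
                prof = profile_sequence(rec.sequence[start:end], k)
            except ValueError:
                logger.warning(
                    "fragment %s[%d:%d] has no countable windows; skipped",
                    rec.scaffold_id,
                    start,
                    end,
                )
                continue
            fragments.append(
                Fragment(
                    fragment_id=f"{rec.scaffold_id}|{ordinal}",
                    scaffold_id=rec.scaffold_id,
                    start_bp=start,
                    end_bp=end,
                    freqs=prof.freqs,
                )
            )
            ordinal += 1
    return FragmentSet(fragments, window_bp, min_fragment_bp, k)


@dataclass
class CompositionOutlierResult:
    """Verdict of the composition (k-mer signature) bin-membership test."""

    scaffold_id: str
    distance: float
    robust_z: float
    is_outlier: bool
    low_power: bool = False
    threshold: float = 3.0


# Relative floor on the robust scale of member distances: bins of near-clonal
# scaffolds otherwise collapse the MAD to ~0 and flag meaningless deviations.
MIN_RELATIVE_SCALE = 0.05


def _median_profile(freqs: np.ndarray) -> np.ndarray:
    med = np.median(freqs, axis=0)
    s = med.sum()
    if s <= 0:
        raise ValueError("degenerate median profile")
    return med / s


def _loo_scaled_distances(
    freqs: np.ndarray, n_windows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out L1 distances and their variance-balanced versions.

    Each scaffold is compared with the renormalized per-dimension median of
    the *other* members, so every distance excludes its own profile and the
    set is exchangeable. The distance is then divided by
    ``sqrt(1/n_i + 1/n_ref)``: the first term is the scaffold's own sampling
    noise (frequency error shrinks like 1/sqrt(windows), so raw distances of
    short scaffolds are inflated), the second the noise of the median
    reference itself (which dominates for long scaffolds). ``n_ref`` is the
    effective window count behind a median of B-1 profiles (harmonic mean,
    with the 2/pi efficiency of the median).
    """
    B = len(freqs)
    n_ref = (2.0 / math.pi) * (B - 1) ** 2 / float(np.sum(1.0 / n_windows))
    d = np.empty(B)
    for i in range(B):
        ref = _median_profile(np.delete(freqs, i, axis=0))
        d[i] = np.abs(freqs[i] - ref).sum()
    t = d / np.sqrt(1.0 / n_windows + 1.0 / n_ref)
    return d, t


def composition_membership_tests(
    bin_records: Sequence[ScaffoldRecord],
    k: int = 4,
    z_threshold: float = 3.0,
    profiles: dict[str, KmerProfile] | None = None,
) -> dict[str, CompositionOutlierResult]:
    """Composition membership test for every scaffold of one bin.

    Each scaffold's robust z compares its scaled leave-one-out distance with
    the other members' scaled distances (median / 1.4826 x MAD); a scaffold
    is an outlier when z exceeds ``z_threshold``.
    """
    if len(bin_records) < 2:
        raise ValueError("membership test undefined for a bin of size 1")
    ids = [r.scaffold_id for r in bin_records]
    if profiles is None:
        profiles = {
            r.scaffold_id: profile_sequence(r.sequence, k) for r in bin_records
        }
    freqs = np.vstack([profiles[i].freqs for i in ids])
    n_windows = np.array([profiles[i].n_windows for i in ids], dtype=float)
    d, t = _loo_scaled_distances(freqs, n_windows)
    results: dict[str, CompositionOutlierResult] = {}
    for qi, query_id in enumerate(ids):
        null = np.delete(t, qi)
        med = float(np.median(null))
        mad = float(np.median(np.abs(null - med)))
        scale = max(1.4826 * mad, MIN_RELATIVE_SCALE * med)
        z = (t[qi] - med) / scale if scale > 0 else 0.0
        results[query_id] = CompositionOutlierResult(
            scaffold_id=query_id,
            distance=float(d[qi]),
            robust_z=z,
            is_outlier=z > z_threshold,
            low_power=len(ids) < 5,
            threshold=z_threshold,
        )
    return results


def composition_membership_test(
    query_id: str,
    bin_records: Sequence[ScaffoldRecord],
    k: int = 4,
    z_threshold: float = 3.0,
    profiles: dict[str, KmerProfile] | None = None,
) -> CompositionOutlierResult:
    """Test whether one scaffold's k-mer signature fits its bin.

    See :func:`composition_membership_tests` for the statistic; this runs the
    bin-wide computation and returns the query's result.
    """
    ids = [r.scaffold_id for r in bin_records]
    if query_id not in ids:
        raise ValueError(f"query {query_id!r} not in bin")
    return composition_membership_tests(bin_records, k, z_threshold, profiles)[
        query_id
    ]


def profile_matrix(
    items: Sequence[tuple[str, np.ndarray]], k: int
) -> "pd.DataFrame":  # noqa: F821
    """Profile matrix as a DataFrame (rows = ids, columns = canonical k-mers)."""
    import pandas as pd

    return pd.DataFrame(
        np.vstack([v for _, v in items]),
        index=[i for i, _ in items],
        columns=list(canonical_kmer_index(k)),
    )
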