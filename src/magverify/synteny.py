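"""Gene-arrangement (synteny) screening for the comammox diagnostic.

Complete ammonia oxidizers (comammox) carry AOB-type ammonia oxidation genes
(*amoCAB*, *hao*) inside an otherwise nitrite-oxidizer genome, with
arrangements that discriminate them from canonical AOB: a cytochrome-c
maturation block (*ccmA*-*ccmH*) directly preceding the *hao* cluster, and a
*bfr*-*bfr*-*amoD*-*amoD*-*amoE*-*copC*-*copD* accessory cluster. Partial
genes at facing scaffold termini additionally suggest scaffold joins.

Internally all coordinates are 0-based half-open; GFF3 input (1-based
inclusive) is converted on read. Partial flags are stored in scaffold
coordinates: ``partial_5p`` = truncated on the lower-coordinate side,
``partial_3p`` = truncated on the higher-coordinate side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

KNOWN_LABELS = frozenset(
    ["amoA", "amoB", "amoC", "amoD", "amoE", "hao", "orfM", "bfr", "copC", "copD"]
    + [f"ccm{x}" for x in "ABCDEFGH"]
)

CCM_LABELS = frozenset(f"ccm{x}" for x in "ABCDEFGH")

# product-description keywords -> controlled label (lowercase substring match)
DEFAULT_PRODUCT_KEYWORDS: dict[str, str] = {
    "hydroxylamine dehydrogenase": "hao",
    "hydroxylamine oxidoreductase": "hao",
    "ammonia monooxygenase subunit a": "amoA",
    "ammonia monooxygenase subunit b": "amoB",
    "ammonia monooxygenase subunit c": "amoC",
    "bacterioferritin": "bfr",
    "copper resistance protein c": "copC",
    "copper resistance protein d": "copD",
    "cytochrome c maturation protein ccma": "ccmA",
    "cytochrome c maturation protein ccmb": "ccmB",
    "cytochrome c maturation protein ccmc": "ccmC",
    "cytochrome c maturation protein ccmd": "ccmD",
    "cytochrome c maturation protein ccme": "ccmE",
    "cytochrome c maturation protein ccmf": "ccmF",
    "cytochrome c maturation protein ccmg": "ccmG",
    "cytochrome c maturation protein ccmh": "ccmH",
}


@dataclass
class GeneFeature:
    scaffold_id: str
    start_bp: int
    end_bp: int
    strand: str
    label: str
    partial_5p: bool = False
    partial_3p: bool = False
    feature_id: str | None = None

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"feature {self.feature_id or self.label}: end <= start "
                f"({self.start_bp}, {self.end_bp})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class GenePattern:
    """Ordered arrangement pattern: each element is (label set, min, max
    multiplicity); gaps are limited in genes and in base pairs."""

    pattern_id: str
    elements: list[tuple[frozenset[str], int, int]]
    max_intervening_genes: int = 5
    max_gap_bp: int = 10000
    orientation_mode: str = "any"  # or "co-oriented"

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValueError("pattern needs >= 2 elements")
        for labels, lo, hi in self.elements:
            if lo < 1 or hi < lo:
                raise ValueError("multiplicities must satisfy 1 <= min <= max")


@dataclass
class PatternMatch:
    pattern_id: str
    scaffold_id: str
    span_start_bp: int
    span_end_bp: int
    matched_features: list[GeneFeature]
    n_intervening: int
    reversed_order: bool = False


@dataclass
class JoinCandidate:
    scaffold_a: str
    scaffold_b: str
    label: str
    a_terminal: str  # "3p" | "5p" (scaffold coordinates)
    b_terminal: str
    strand_compatible: bool


def _normalize_label(raw: str, keyword_map: Mapping[str, str]) -> str:
    token = raw.strip()
    if token in KNOWN_LABELS:
        return token
    low = token.lower()
    if low in {l.lower() for l in KNOWN_LABELS}:
        for l in KNOWN_LABELS:
            if l.lower() == low:
                return l
    for kw, label in keyword_map.items():
        if kw in low:
            return label
    return f"other:{token}"


def _parse_gff3(path: str | Path, label_key: str, keyword_map: Mapping[str, str]):
    import gffutils.feature

    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = gffutils.feature.feature_from_line(line)
            if f.end < f.start:
                raise ValueError(f"{path}:{lineno}: end < start")
            attrs = {k: v[0] for k, v in f.attributes.items() if v}
            raw = attrs.get(label_key) or attrs.get("product") or f.id or ""
            label = _normalize_label(raw, keyword_map)
            partial = attrs.get("partial", "").lower()
            feats.append(
                GeneFeature(
                    scaffold_id=f.seqid,
                    start_bp=f.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                    end_bp=f.end,
                    strand=f.strand if f.strand in "+-" else "+",
                    label=label,
                    partial_5p="5p" in partial or partial == "true",
                    partial_3p="3p" in partial or partial == "true",
                    feature_id=attrs.get("ID"),
                )
            )
    return feats


def _parse_tsv(path: str | Path, keyword_map: Mapping[str, str]):
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"scaffold_id", "start_bp", "end_bp", "strand", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: TSV needs columns {sorted(required)}")
    feats = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        start, end = int(row.start_bp), int(row.end_bp)
        if end < start:
            raise ValueError(f"{path}:{lineno}: end < start")
        partial = str(getattr(row, "partial", "") or "").lower()
        feats.append(
            GeneFeature(
                scaffold_id=row.scaffold_id,
                start_bp=start,
                end_bp=end,
                strand=row.strand,
                label=_normalize_label(row.label, keyword_map),
                partial_5p="5p" in partial,
                partial_3p="3p" in partial,
            )
        )
    return feats


def read_features(
    path: str | Path,
    label_key: str = "gene",
    keyword_map: Mapping[str, str] | None = None,
) -> list[GeneFeature]:
    """Read gene features from GFF3 (1-based, converted) or TSV (0-based).

    Labels come from the ``label_key`` GFF attribute, falling back to a
    keyword map over ``product``; unrecognized labels become ``other:<text>``.
    """
    keyword_map = DEFAULT_PRODUCT_KEYWORDS if keyword_map is None else keyword_map
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        feats = _parse_gff3(path, label_key, keyword_map)
    else:
        feats = _parse_tsv(path, keyword_map)
    feats.sort(key=lambda f: (f.scaffold_id, f.start_bp))
    return feats


def _label_matches(label: str, label_set: frozenset[str]) -> bool:
    return label in label_set


def _search_matches(
    features: Sequence[GeneFeature],
    elements: list[tuple[frozenset[str], int, int]],
    max_intervening: int,
    max_gap_bp: int,
    co_oriented: bool,
) -> list[list[int]]:
    """Backtracking search: all minimal matches, one per viable start index.

    Each element consumes exactly its minimum multiplicity of features (the
    minimal-window convention); between consecutive matched features at most
    ``max_intervening`` unmatched genes and ``max_gap_bp`` bp may intervene.
    """
    n = len(features)
    needed = [(labels, lo) for labels, lo, _hi in elements]

    def gap_ok(i: int, j: int) -> bool:
        # both limits are monotone in j for sorted features, so a violation
        # here means every later j also violates
        return (
            j - i - 1 <= max_intervening
            and features[j].start_bp - features[i].end_bp <= max_gap_bp
        )

    def dfs(elem_idx: int, count: int, last: int, chosen: list[int]) -> list[int] | None:
        if elem_idx == len(needed):
            return chosen
        labels, lo = needed[elem_idx]
        for j in range(last + 1, n):
            if not gap_ok(last, j):
                break
            if co_oriented and features[j].strand != features[last].strand:
                continue
            if _label_matches(features[j].label, labels):
                nxt_elem, nxt_count = (
                    (elem_idx, count + 1) if count + 1 < lo else (elem_idx + 1, 0)
                )
                res = dfs(nxt_elem, nxt_count, j, chosen + [j])
                if res is not None:
                    return res
        return None

    matches = []
    first_labels, first_lo = needed[0]
    for i in range(n):
        if _label_matches(features[i].label, first_labels):
            nxt = (0, 1) if first_lo > 1 else (1, 0)
            res = dfs(nxt[0], nxt[1], i, [i])
            if res is not None:
                matches.append(res)
    return matches


def match_pattern(
    features: Sequence[GeneFeature], pattern: GenePattern
) -> list[PatternMatch]:
    """Find minimal windows matching the pattern left-to-right, and in exact
    reverse element order (reported with ``reversed_order=True``).

    Overlapping matches are deduplicated: a match whose span strictly contains
    another reported match's span is dropped.
    """
    feats = sorted(features, key=lambda f: f.start_bp)
    co = pattern.orientation_mode == "co-oriented"
    raw: list[tuple[list[int], bool]] = []
    for idxs in _search_matches(
        feats, pattern.elements, pattern.max_intervening_genes, pattern.max_gap_bp, co
    ):
        raw.append((idxs, False))
    rev_elements = list(reversed(pattern.elements))
    if rev_elements != pattern.elements:
        for idxs in _search_matches(
            feats, rev_elements, pattern.max_intervening_genes, pattern.max_gap_bp, co
        ):
            raw.append((idxs, True))

    matches = []
    for idxs, rev in raw:
        span = (feats[idxs[0]].start_bp, feats[idxs[-1]].end_bp)
        matches.append(
            PatternMatch(
                pattern_id=pattern.pattern_id,
                scaffold_id=feats[idxs[0]].scaffold_id,
                span_start_bp=span[0],
                span_end_bp=span[1],
                matched_features=[feats[j] for j in idxs],
                n_intervening=idxs[-1] - idxs[0] + 1 - len(idxs),
                reversed_order=rev,
            )
        )
    # minimal-span dedup
    kept = []
    for m in sorted(matches, key=lambda m: m.span_end_bp - m.span_start_bp):
        if not any(
            m.span_start_bp <= k.span_start_bp and k.span_end_bp <= m.span_end_bp
            and (m.span_start_bp, m.span_end_bp) != (k.span_start_bp, k.span_end_bp)
            for k in kept
        ):
            kept.append(m)
    kept.sort(key=lambda m: m.span_start_bp)
    return kept


AMO_CLUSTER = GenePattern(
    "P1_amoCAB",
    [(frozenset({"amoC"}), 1, 2), (frozenset({"amoA"}), 1, 1), (frozenset({"amoB"}), 1, 1)],
)
ACCESSORY_CLUSTER = GenePattern(
    "P3_bfr_amoDE_copCD",
    [
        (frozenset({"bfr"}), 2, 2),
        (frozenset({"amoD"}), 2, 2),
        (frozenset({"amoE"}), 1, 1),
        (frozenset({"copC"}), 1, 1),
        (frozenset({"copD"}), 1, 1),
    ],
)

CCM_MIN_DISTINCT = 4


def _ccm_before_hao(
    features: Sequence[GeneFeature], max_intervening: int, max_gap_bp: int
) -> list[PatternMatch]:
    """P2: a cytochrome-c maturation block (>= CCM_MIN_DISTINCT distinct
    ccmA-H labels) directly preceding hao, in either reading direction."""
    feats = sorted(features, key=lambda f: f.start_bp)
    out = []
    for direction, rev in ((1, False), (-1, True)):
        order = feats if direction == 1 else feats[::-1]
        for hi, f in enumerate(order):
            if f.label != "hao":
                continue
            # walk backwards from hao collecting the ccm block
            distinct: set[str] = set()
            idxs = []
            skipped = 0
            prev = f
            for g in reversed(order[:hi]):
                gap = (
                    prev.start_bp - g.end_bp if direction == 1 else g.start_bp - prev.end_bp
                )
                if gap > max_gap_bp:
                    break
                if g.label in CCM_LABELS:
                    distinct.add(g.label)
                    idxs.append(g)
                    prev = g
                    skipped = 0
                else:
                    skipped += 1
                    if skipped > max_intervening:
                        break
            if len(distinct) >= CCM_MIN_DISTINCT:
                block = idxs + [f]
                out.append(
                    PatternMatch(
                        pattern_id="P2_ccm_hao",
                        scaffold_id=f.scaffold_id,
                        span_start_bp=min(g.start_bp for g in block),
                        span_end_bp=max(g.end_bp for g in block),
                        matched_features=sorted(block, key=lambda g: g.start_bp),
                        n_intervening=0,
                        reversed_order=rev,
                    )
                )
                break  # one match per direction suffices
        if out and not rev:
            break
    return out


@dataclass
class ComammoxScreenReport:
    pattern_matches: dict[str, list[PatternMatch]]
    tier: str  # "full" | "partial" | "absent"

    @property
    def patterns_present(self) -> list[str]:
        return [p for p, ms in self.pattern_matches.items() if ms]


def screen_comammox(
    features: Sequence[GeneFeature],
    max_intervening: int = 5,
    max_gap_bp: int = 10000,
) -> ComammoxScreenReport:
    """Evaluate the three shipped comammox arrangement patterns over a bin.

    P1: amoC-amoA-amoB cluster; P2: ccm block (>= 4 distinct ccmA-H) preceding
    hao; P3: bfr x2, amoD x2, amoE, copC, copD. Tier: full = all three,
    partial = at least one, absent = none.
    """
    by_scaffold: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_scaffold.setdefault(f.scaffold_id, []).append(f)
    results: dict[str, list[PatternMatch]] = {
        "P1_amoCAB": [],
        "P2_ccm_hao": [],
        "P3_bfr_amoDE_copCD": [],
    }
    for sid, feats in sorted(by_scaffold.items()):
        results["P1_amoCAB"] += match_pattern(feats, AMO_CLUSTER)
        results["P2_ccm_hao"] += _ccm_before_hao(feats, max_intervening, max_gap_bp)
        results["P3_bfr_amoDE_copCD"] += match_pattern(feats, ACCESSORY_CLUSTER)
    n = sum(bool(v) for v in results.values())
    tier = "full" if n == 3 else ("partial" if n >= 1 else "absent")
    return ComammoxScreenReport(pattern_matches=results, tier=tier)


def find_join_candidates(
    features: Sequence[GeneFeature],
    scaffold_lengths: Mapping[str, int],
    end_window_bp: int = 1000,
) -> list[JoinCandidate]:
    """Pair terminal partial genes with matching labels across scaffolds.

    A feature qualifies as right-terminal (scaffold "3p") when flagged
    ``partial_3p`` and ending within ``end_window_bp`` of the scaffold end,
    left-terminal ("5p") when flagged ``partial_5p`` and starting within
    ``end_window_bp`` of position 0. Candidates join a right terminal to a
    left terminal with the same label; symmetric duplicates are removed.
    """
    right, left = [], []
    for f in features:
        L = scaffold_lengths.get(f.scaffold_id)
        if L is None:
            continue
        if f.partial_3p and L - f.end_bp <= end_window_bp:
            right.append(f)
        if f.partial_5p and f.start_bp <= end_window_bp:
            left.append(f)
    out = []
    seen = set()
    for a in right:
        for b in left:
            if a.scaffold_id == b.scaffold_id or a.label != b.label:
                continue
            if a.label.startswith("other:"):
                continue
            key = frozenset(
                {(a.scaffold_id, "3p", a.label), (b.scaffold_id, "5p", b.label)}
            )
            if key in seen:
                continue
            seen.add(key)
            out.append(
                JoinCandidate(
                    scaffold_a=a.scaffold_id,
                    scaffold_b=b.scaffold_id,
                    label=a.label,
                    a_terminal="3p",
                    b_terminal="5p",
                    strand_compatible=a.strand == b.strand,
                )
            )
    out.sort(key=lambda j: (j.scaffold_a, j.scaffold_b, j.label))
    return out
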