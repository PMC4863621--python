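"""Synthetic metagenome communities with known truth.

Every verification stage in this package is exercised against communities
generated here: several genomes with distinct oligonucleotide composition
(order-2 Markov chains with genome-specific transition biases and staggered
GC targets), lognormal multi-sample abundances with negative-binomial
per-base depth, planted mis-binned scaffolds, planted chimeric scaffolds
with coverage-anomalous windows, and planted comammox-style gene
arrangements. Coverage is simulated directly as depth (no reads), which is
what the verification stages consume.

All randomness descends from one integer seed via ``numpy`` SeedSequence
spawning; outputs are byte-stable per seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .coverage import DepthTrack, write_depth_bedgraph
from .seqio import ScaffoldRecord, write_fasta, write_bin_table
from .synteny import GeneFeature

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class GenomeModel:
    """Order-2 Markov sequence model with a genome-specific bias signature."""

    genome_id: str
    length_bp: int
    gc_target: float
    markov_order: int = 2
    bias_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.3 <= self.gc_target <= 0.7:
            raise ValueError("gc_target must be in [0.3, 0.7]")


def _transition_cumulative(theta: float, bias: np.ndarray) -> list[list[float]]:
    """Cumulative next-base probabilities for each of the 16 dinucleotide
    contexts; rows = softmax of a GC-tilted base law times exp(bias)."""
    base = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
    rows = base[None, :] * np.exp(bias)
    rows /= rows.sum(axis=1, keepdims=True)
    return np.cumsum(rows, axis=1).tolist()


def _markov_chain(length: int, cum: list[list[float]], rng: np.random.Generator) -> str:
    u = rng.random(length).tolist()
    out = bytearray(length)
    bases = b"ACGT"
    ctx = 0
    for i in range(length):
        ui = u[i]
        row = cum[ctx]
        if ui < row[0]:
            b = 0
        elif ui < row[1]:
            b = 1
        elif ui < row[2]:
            b = 2
        else:
            b = 3
        out[i] = bases[b]
        ctx = ((ctx << 2) | b) & 15
    return out.decode("ascii")


def simulate_genome(model: GenomeModel) -> str:
    """Generate one genome; the realized GC is rejection-adjusted to within
    +/- 0.02 of the target (at most 10 adjustment rounds)."""
    if model.length_bp < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = np.random.default_rng(model.seed)
    bias = rng.normal(0.0, model.bias_sd, size=(16, 4))
    theta = model.gc_target
    for _round in range(10):
        seq = _markov_chain(model.length_bp, _transition_cumulative(theta, bias), rng)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        if abs(gc - model.gc_target) <= 0.02:
            return seq
        theta = float(np.clip(theta + (model.gc_target - gc), 0.05, 0.95))
    raise RuntimeError(
        f"genome {model.genome_id}: gc_target {model.gc_target} unreachable"
    )


def fragment_genome(
    sequence: str,
    rng: np.random.Generator,
    median_bp: int = 40_000,
    sigma_log: float = 0.6,
    min_bp: int = 5_000,
) -> list[str]:
    """Cut a genome into consecutive scaffolds with lognormal lengths
    (median ``median_bp``); a terminal remainder < ``min_bp`` is merged into
    the previous scaffold. Scaffolds tile the genome exactly."""
    if len(sequence) < min_bp:
        raise ValueError("sequence shorter than minimum scaffold length")
    cuts = [0]
    while cuts[-1] < len(sequence):
        ln = int(rng.lognormal(np.log(median_bp), sigma_log))
        cuts.append(cuts[-1] + max(min_bp, ln))
    cuts[-1] = len(sequence)
    if len(cuts) > 2 and cuts[-1] - cuts[-2] < min_bp:
        del cuts[-2]
    return [sequence[a:b] for a, b in zip(cuts[:-1], cuts[1:])]


@dataclass
class AbundanceModel:
    n_samples: int = 4
    depth_scale: float = 30.0
    nb_size: float | None = 10.0  # None -> Poisson
    lognormal_sigma: float = 1.0


@dataclass
class CommunityTruth:
    scaffold_genome: dict[str, str]
    planted_misbinned: list[tuple[str, str, str]] = field(default_factory=list)
    chimeras: list[tuple[str, int, tuple[str, str]]] = field(default_factory=list)
    coverage_anomalies: list[tuple[str, int, int, float]] = field(default_factory=list)
    annotations: list[GeneFeature] = field(default_factory=list)


@dataclass
class CommunityConfig:
    n_genomes: int = 8
    genome_length_bp: int = 500_000
    n_misbinned: int = 3
    n_chimeras: int = 2
    chimera_segment_bp: int = 15_000
    chimera_multiplier: float = 3.0
    anomaly_halfwidth_bp: int = 1_000
    annotations: str = "comammox"  # "comammox" | "aob_like" | "none"
    bias_sd: float = 0.5
    gc_range: tuple[float, float] = (0.35, 0.65)
    scaffold_median_bp: int = 40_000
    scaffold_sigma_log: float = 0.6
    scaffold_min_bp: int = 5_000
    abundance: AbundanceModel = field(default_factory=AbundanceModel)


@dataclass
class Community:
    config: CommunityConfig
    bins: dict[str, list[ScaffoldRecord]]
    truth: CommunityTruth
    abundance: pd.DataFrame  # genomes x samples

    def all_records(self) -> list[ScaffoldRecord]:
        return [r for recs in self.bins.values() for r in recs]

    def scaffold_lengths(self) -> dict[str, int]:
        return {r.scaffold_id: len(r) for r in self.all_records()}


def plant_misbinned(
    bins: dict[str, list[ScaffoldRecord]],
    truth: CommunityTruth,
    n: int,
    rng: np.random.Generator,
    frozen: set[str] = frozenset(),
) -> None:
    """Move ``n`` scaffolds into a wrong bin (sequences unchanged), updating
    the truth in place. Scaffolds in ``frozen`` are never moved and every
    source bin keeps at least 5 members."""
    if n == 0:
        return
    if len(bins) < 2:
        raise ValueError("need >= 2 bins to plant mis-binned scaffolds")
    bin_ids = sorted(bins)
    movable = [
        r.scaffold_id
        for b in bin_ids
        for r in bins[b]
        if r.scaffold_id not in frozen and len(bins[b]) > 5
    ]
    if n > len(movable):
        raise ValueError(f"cannot move {n} scaffolds; only {len(movable)} movable")
    chosen = [str(s) for s in rng.choice(movable, size=n, replace=False)]
    for sid in chosen:
        src = next(b for b in bin_ids if any(r.scaffold_id == sid for r in bins[b]))
        dst = str(rng.choice([b for b in bin_ids if b != src]))
        rec = next(r for r in bins[src] if r.scaffold_id == sid)
        bins[src].remove(rec)
        bins[dst].append(ScaffoldRecord(rec.scaffold_id, rec.sequence, dst))
        truth.planted_misbinned.append((sid, dst, truth.scaffold_genome[sid]))


def plant_chimera(segment_a: str, segment_b: str) -> tuple[str, int]:
    """Concatenate two segments into a chimeric scaffold; returns the
    sequence and the recorded breakpoint (= len(segment_a))."""
    if len(segment_a) < 10_000 or len(segment_b) < 10_000:
        raise ValueError("chimera segments must be >= 10 kb")
    return segment_a + segment_b, len(segment_a)


def _comammox_features(s1: str, len1: int, s2: str, len2: int) -> list[GeneFeature]:
    """Plant the diagnostic comammox arrangement on two scaffolds:

    scaffold 1 — ccmA..ccmH block, hao cluster, then amoC/amoA/amoB in close
    succession, ending in a 3'-terminal partial amoC; scaffold 2 — the
    accessory cluster laid out reversed in scaffold coordinates (5'-terminal
    partial amoC, then copD, copC, amoE, amoD x2, bfr x2), reproducing the
    copD-then-partial-amoC reading order at the scaffold's 5' end.
    """
    feats: list[GeneFeature] = []
    pos = 500

    def add(sid: str, label: str, length: int, gap: int = 150, **kw) -> None:
        nonlocal pos
        feats.append(GeneFeature(sid, pos, pos + length, "+", label, **kw))
        pos += length + gap

    for x in "ABCDEFGH":
        add(s1, f"ccm{x}", 600)
    add(s1, "other:hypothetical", 700)
    add(s1, "hao", 1700)
    add(s1, "other:cytochrome c554", 800)
    add(s1, "other:hypothetical", 650)
    add(s1, "orfM", 900)
    add(s1, "amoC", 810)
    add(s1, "amoA", 830)
    add(s1, "amoB", 1250)
    feats.append(GeneFeature(s1, len1 - 400, len1, "+", "amoC", partial_3p=True))

    feats.append(GeneFeature(s2, 0, 350, "+", "amoC", partial_5p=True))
    pos = 500
    for label, ln in [
        ("copD", 930),
        ("copC", 390),
        ("amoE", 780),
        ("amoD", 660),
        ("amoD", 660),
        ("bfr", 480),
        ("bfr", 480),
    ]:
        add(s2, label, ln)
    return feats


def _aob_like_features(s1: str, len1: int) -> list[GeneFeature]:
    """amo cluster and hao without a preceding ccm block (canonical AOB)."""
    feats: list[GeneFeature] = []
    pos = 500

    def add(label: str, length: int, gap: int = 150) -> None:
        nonlocal pos
        feats.append(GeneFeature(s1, pos, pos + length, "+", label))
        pos += length + gap

    add("other:hypothetical", 700)
    add("other:cytochrome c552", 600)
    add("hao", 1700)
    add("other:hypothetical", 650)
    add("amoC", 810)
    add("amoA", 830)
    add("amoB", 1250)
    return feats


def plant_annotations(
    bins: dict[str, list[ScaffoldRecord]],
    truth: CommunityTruth,
    arrangement: str,
    target_bin: str,
) -> None:
    """Write the chosen gene arrangement onto the target bin's two longest
    scaffolds and record it in the truth."""
    if arrangement == "none":
        return
    recs = sorted(bins[target_bin], key=len, reverse=True)
    if arrangement == "comammox":
        if len(recs) < 2 or len(recs[0]) < 30_000 or len(recs[1]) < 12_000:
            raise ValueError("comammox arrangement needs scaffolds >= 30 kb and 12 kb")
        feats = _comammox_features(
            recs[0].scaffold_id, len(recs[0]), recs[1].scaffold_id, len(recs[1])
        )
    elif arrangement == "aob_like":
        if len(recs[0]) < 30_000:
            raise ValueError("aob_like arrangement needs a scaffold >= 30 kb")
        feats = _aob_like_features(recs[0].scaffold_id, len(recs[0]))
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    truth.annotations.extend(feats)


def simulate_community(
    config: CommunityConfig | None = None, seed: int = 1
) -> Community:
    """Build the full in-memory benchmark community.

    Defaults: 8 genomes x 0.5 Mb, 4 samples, 3 planted mis-binned scaffolds,
    2 chimeras (one with a 3x coverage window straddling its breakpoint),
    and the comammox arrangement planted on bin g1.
    """
    config = config or CommunityConfig()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(4)
    genome_seeds = np.random.SeedSequence(seed).generate_state(config.n_genomes) % (
        2**31
    )

    gcs = np.linspace(*config.gc_range, config.n_genomes)
    genomes: dict[str, str] = {}
    for i in range(config.n_genomes):
        gid = f"g{i + 1}"
        genomes[gid] = simulate_genome(
            GenomeModel(
                genome_id=gid,
                length_bp=config.genome_length_bp,
                gc_target=float(gcs[i]),
                bias_sd=config.bias_sd,
                seed=int(genome_seeds[i]),
            )
        )

    frag_rng = np.random.default_rng(child[0])
    bins: dict[str, list[ScaffoldRecord]] = {}
    truth = CommunityTruth(scaffold_genome={})
    for gid, seq in genomes.items():
        bin_id = f"bin_{gid}"
        pieces = fragment_genome(
            seq,
            frag_rng,
            median_bp=config.scaffold_median_bp,
            sigma_log=config.scaffold_sigma_log,
            min_bp=config.scaffold_min_bp,
        )
        bins[bin_id] = [
            ScaffoldRecord(f"{gid}_s{j:03d}", piece, bin_id)
            for j, piece in enumerate(pieces, 1)
        ]
        for rec in bins[bin_id]:
            truth.scaffold_genome[rec.scaffold_id] = gid

    # chimeras: segments from two donor genomes, housed in donor A's bin
    chim_rng = np.random.default_rng(child[1])
    gids = sorted(genomes)
    for c in range(config.n_chimeras):
        ga, gb = (str(g) for g in chim_rng.choice(gids, size=2, replace=False))
        seg = config.chimera_segment_bp
        off_a = int(chim_rng.integers(0, len(genomes[ga]) - seg))
        off_b = int(chim_rng.integers(0, len(genomes[gb]) - seg))
        seq, breakpoint = plant_chimera(
            genomes[ga][off_a : off_a + seg], genomes[gb][off_b : off_b + seg]
        )
        sid = f"chimera_{c + 1}"
        bins[f"bin_{ga}"].append(ScaffoldRecord(sid, seq, f"bin_{ga}"))
        truth.scaffold_genome[sid] = ga
        truth.chimeras.append((sid, breakpoint, (ga, gb)))
        if c == 0:  # one chimera carries a collapsed-repeat-style 3x window
            truth.coverage_anomalies.append(
                (
                    sid,
                    breakpoint - config.anomaly_halfwidth_bp,
                    breakpoint + config.anomaly_halfwidth_bp,
                    config.chimera_multiplier,
                )
            )

    if config.annotations != "none":
        plant_annotations(bins, truth, config.annotations, "bin_g1")

    frozen = {f.scaffold_id for f in truth.annotations} | {
        c[0] for c in truth.chimeras
    }
    plant_misbinned(
        bins, truth, config.n_misbinned, np.random.default_rng(child[2]), frozen
    )

    ab_rng = np.random.default_rng(child[3])
    sigma = config.abundance.lognormal_sigma
    abundance = pd.DataFrame(
        ab_rng.lognormal(0.0, sigma, size=(config.n_genomes, config.abundance.n_samples)),
        index=gids,
        columns=[f"sample_{s + 1}" for s in range(config.abundance.n_samples)],
    )
    return Community(config=config, bins=bins, truth=truth, abundance=abundance)


def simulate_depth_tracks(
    community: Community, seed: int = 1, smooth_bp: int = 100
) -> list[DepthTrack]:
    """Per-base depth for every (scaffold, sample).

    Depth ~ NegBin(mean = depth_scale x abundance[genome, sample], size)
    i.i.d. per base, planted anomaly windows multiplied before noise, then a
    ``smooth_bp`` moving average mimics read-length autocorrelation.
    """
    cfg = community.config.abundance
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    anomalies: dict[str, list[tuple[int, int, float]]] = {}
    for sid, a, b, mult in community.truth.coverage_anomalies:
        anomalies.setdefault(sid, []).append((a, b, mult))

    tracks: list[DepthTrack] = []
    for sample in community.abundance.columns:
        for rec in community.all_records():
            gid = community.truth.scaffold_genome[rec.scaffold_id]
            mean = cfg.depth_scale * float(community.abundance.loc[gid, sample])
            L = len(rec)
            m = np.full(L, mean)
            for a, b, mult in anomalies.get(rec.scaffold_id, []):
                m[max(0, a) : min(L, b)] *= mult
            if mean <= 0:
                depth = np.zeros(L, dtype=np.int64)
            else:
                if cfg.nb_size is None:
                    raw = rng.poisson(m)
                else:
                    p = cfg.nb_size / (cfg.nb_size + m)
                    raw = rng.negative_binomial(cfg.nb_size, p)
                depth = np.rint(
                    uniform_filter1d(raw.astype(float), size=smooth_bp, mode="nearest")
                ).astype(np.int64)
            tracks.append(DepthTrack(rec.scaffold_id, sample, depth))
    return tracks


def write_gff3(features: Sequence[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features, 1):
            partial = []
            if f.partial_5p:
                partial.append("5p")
            if f.partial_3p:
                partial.append("3p")
            attrs = f"ID=feat{i};gene={f.label}"
            if partial:
                attrs += f";partial={','.join(partial)}"
            fh.write(
                f"{f.scaffold_id}\tmagverify\tgene\t{f.start_bp + 1}\t{f.end_bp}\t."
                f"\t{f.strand}\t.\t{attrs}\n"
            )


def make_benchmark(
    outdir: str | Path,
    config: CommunityConfig | None = None,
    seed: int = 1,
    force: bool = False,
) -> Community:
    """Write the benchmark dataset to disk: one FASTA per bin, a bin TSV, one
    bedGraph per sample, a GFF3 of planted annotations, and a truth manifest
    JSON. Fully reproducible per seed."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    community = simulate_community(config, seed)
    for bin_id, recs in sorted(community.bins.items()):
        write_fasta(recs, outdir / f"{bin_id}.fasta")
    write_bin_table(community.all_records(), outdir / "bins.tsv")

    tracks = simulate_depth_tracks(community, seed)
    by_sample: dict[str, list[DepthTrack]] = {}
    for t in tracks:
        by_sample.setdefault(t.sample_id, []).append(t)
    for sample, ts in sorted(by_sample.items()):
        write_depth_bedgraph(ts, outdir / f"depth_{sample}.bedGraph")

    if community.truth.annotations:
        write_gff3(community.truth.annotations, outdir / "annotations.gff3")

    truth = community.truth
    manifest = {
        "seed": seed,
        "config": _config_to_dict(community.config),
        "scaffold_genome": truth.scaffold_genome,
        "planted_misbinned": [list(x) for x in truth.planted_misbinned],
        "chimeras": [[sid, bp, list(donors)] for sid, bp, donors in truth.chimeras],
        "coverage_anomalies": [list(x) for x in truth.coverage_anomalies],
        "n_annotations": len(truth.annotations),
        "abundance": {
            g: community.abundance.loc[g].round(6).to_dict()
            for g in community.abundance.index
        },
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2))
    return community


def _config_to_dict(config: CommunityConfig) -> dict:
    d = dataclasses.asdict(config)
    d["gc_range"] = list(d["gc_range"])
    return d
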