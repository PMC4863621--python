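"""Orchestration of the verification stages into per-scaffold verdicts.

Bin membership of a scaffold rests on three independent lines of evidence —
composition (k-mer signature vs bin median), differential coverage across
samples, and independent co-binning on an emergent self-organizing map —
plus a per-base coverage screen for misassembly. A scaffold is "flagged"
when any stage flags it and "supported" otherwise; per-stage results are
always reported so the evidence can be weighed line by line. Stages whose
inputs are absent are skipped with a notice rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coverage import (
    CoverageMatrix,
    CoverageOutlierResult,
    DepthTrack,
    MisassemblyRegion,
    coverage_membership_test,
    detect_anomalous_regions,
)
from .esom import (
    EsomVerdict,
    SomConfig,
    assign_bmu,
    default_grid_shape,
    territory_verdict,
    train_som,
)
from .kmer import (
    CompositionOutlierResult,
    composition_membership_tests,
    fragment_scaffolds,
)
from .seqio import ScaffoldRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable knob of the verification pipeline, serialized verbatim
    into reports for provenance."""

    k: int = 4
    fragment_window_bp: int = 5000
    fragment_min_bp: int = 2500
    composition_z_threshold: float = 3.0
    coverage_z_threshold: float = 3.0
    coverage_corr_threshold: float = 0.9
    anomaly_window_bp: int = 1000
    anomaly_step_bp: int = 500
    anomaly_high_fold: float = 2.0
    anomaly_low_fold: float = 0.5
    anomaly_min_region_bp: int = 1000
    territory_dilation_radius: int = 1
    territory_threshold: float = 0.8
    som_epochs: int = 20
    seed: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScaffoldVerdict:
    scaffold_id: str
    composition: CompositionOutlierResult | None
    coverage: CoverageOutlierResult | None
    misassembly_regions: list[MisassemblyRegion] | None
    esom: EsomVerdict | None
    verdict: str  # "supported" | "flagged"
    evidence: list[str]


@dataclass
class VerificationReport:
    bin_id: str
    scaffolds: list[ScaffoldVerdict]
    skipped_stages: list[str]
    config: RunConfig
    version: str = __version__

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.scaffolds:
            rows.append(
                {
                    "scaffold_id": s.scaffold_id,
                    "verdict": s.verdict,
                    "composition_z": None if s.composition is None else round(s.composition.robust_z, 3),
                    "composition_outlier": None if s.composition is None else s.composition.is_outlier,
                    "coverage_corr": None if s.coverage is None else round(s.coverage.profile_correlation, 4),
                    "coverage_max_z": None if s.coverage is None else round(s.coverage.max_abs_robust_z, 3),
                    "coverage_outlier": None if s.coverage is None else s.coverage.is_outlier,
                    "n_anomalous_regions": None
                    if s.misassembly_regions is None
                    else len(s.misassembly_regions),
                    "esom_fraction": None if s.esom is None else round(s.esom.fraction_in_territory, 3),
                    "esom_co_binned": None if s.esom is None else s.esom.co_binned,
                    "evidence": ";".join(s.evidence),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        df = self.to_dataframe()
        return json.dumps(
            {
                "bin_id": self.bin_id,
                "version": self.version,
                "config": self.config.to_dict(),
                "skipped_stages": self.skipped_stages,
                "scaffolds": df.where(df.notna(), None).to_dict(orient="records"),
            },
            indent=2,
            default=str,
        )


@dataclass
class CommunitySom:
    """One ESOM trained on every bin's fragments, reusable across bins."""

    bmus: dict[str, tuple[int, int]]
    frag_scaffold: dict[str, str]
    grid_shape: tuple[int, int]


def train_community_som(
    bins: Mapping[str, Sequence[ScaffoldRecord]], config: RunConfig
) -> CommunitySom | None:
    """Fragment every scaffold of every bin and train one toroidal map."""
    all_records = [r for recs in bins.values() for r in recs]
    fragset = fragment_scaffolds(
        all_records, config.fragment_window_bp, config.fragment_min_bp, config.k
    )
    if len(fragset.fragments) < 10:
        logger.warning("too few fragments for ESOM stage; skipped")
        return None
    X = fragset.feature_matrix()
    rows, cols = default_grid_shape(len(fragset.fragments))
    grid = train_som(
        X, SomConfig(rows=rows, cols=cols, epochs=config.som_epochs, seed=config.seed)
    )
    bmus = assign_bmu(grid, X, fragset.fragment_ids()).bmu
    frag_scaffold = {f.fragment_id: f.scaffold_id for f in fragset.fragments}
    return CommunitySom(bmus=bmus, frag_scaffold=frag_scaffold, grid_shape=grid.shape)


def _esom_verdicts(
    bin_id: str,
    bins: Mapping[str, Sequence[ScaffoldRecord]],
    config: RunConfig,
    som: CommunitySom | None = None,
) -> dict[str, EsomVerdict]:
    """Score each scaffold of the target bin against the territory formed by
    the rest of its bin's fragments on the community map."""
    if som is None:
        som = train_community_som(bins, config)
    if som is None:
        return {}
    bmus, frag_scaffold = som.bmus, som.frag_scaffold
    bin_scaffolds = {r.scaffold_id for r in bins[bin_id]}

    verdicts: dict[str, EsomVerdict] = {}
    for rec in bins[bin_id]:
        query = {
            fid: node
            for fid, node in bmus.items()
            if frag_scaffold[fid] == rec.scaffold_id
        }
        rest = {
            fid: node
            for fid, node in bmus.items()
            if frag_scaffold[fid] in bin_scaffolds
            and frag_scaffold[fid] != rec.scaffold_id
        }
        if not query or len(rest) < 5:
            continue
        verdicts[rec.scaffold_id] = territory_verdict(
            bin_id,
            rec.scaffold_id,
            rest,
            query,
            som.grid_shape,
            dilation_radius=config.territory_dilation_radius,
            threshold=config.territory_threshold,
        )
    return verdicts


def verify_bin(
    bin_id: str,
    bins: Mapping[str, Sequence[ScaffoldRecord]],
    coverage: CoverageMatrix | None = None,
    depth_tracks: Sequence[DepthTrack] | None = None,
    config: RunConfig | None = None,
    run_esom: bool = True,
    som: CommunitySom | None = None,
) -> VerificationReport:
    """Run every available verification stage over one bin's scaffolds.

    Composition always runs; coverage membership requires ``coverage``;
    misassembly screening requires per-base ``depth_tracks``; the ESOM stage
    needs the other bins as context. Missing inputs skip their stage.
    """
    config = config or RunConfig()
    if bin_id not in bins:
        raise ValueError(f"bin {bin_id!r} not found")
    records = list(bins[bin_id])
    skipped: list[str] = []

    member_ids = [r.scaffold_id for r in records]
    comp_results = (
        composition_membership_tests(
            records, k=config.k, z_threshold=config.composition_z_threshold
        )
        if len(records) >= 2
        else {}
    )

    if coverage is not None:
        missing = [m for m in member_ids if m not in coverage.mean_depth.index]
        if missing:
            raise ValueError(f"scaffolds missing from coverage matrix: {missing}")

    tracks_by_scaffold: dict[str, list[DepthTrack]] = {}
    if depth_tracks is not None:
        for t in depth_tracks:
            tracks_by_scaffold.setdefault(t.scaffold_id, []).append(t)
    else:
        skipped.append("misassembly (no per-base depth tracks)")

    if coverage is None:
        skipped.append("coverage-membership (no coverage matrix)")

    esom_verdicts: dict[str, EsomVerdict] = {}
    if run_esom:
        esom_verdicts = _esom_verdicts(bin_id, bins, config, som=som)
        if not esom_verdicts:
            skipped.append("esom (too few fragments)")
    else:
        skipped.append("esom (disabled)")

    scaffolds: list[ScaffoldVerdict] = []
    for rec in records:
        evidence: list[str] = []
        comp = comp_results.get(rec.scaffold_id)
        if comp is not None:
            if comp.is_outlier:
                evidence.append(
                    f"composition: L1 robust z = {comp.robust_z:.2f} > "
                    f"{config.composition_z_threshold}"
                )
        cov = None
        if coverage is not None and coverage.mean_depth.shape[1] >= 2:
            cov = coverage_membership_test(
                rec.scaffold_id,
                coverage,
                member_ids,
                z_threshold=config.coverage_z_threshold,
                corr_threshold=config.coverage_corr_threshold,
            )
            if cov.is_outlier:
                evidence.append(
                    f"coverage: corr = {cov.profile_correlation:.3f}, "
                    f"max |z| = {cov.max_abs_robust_z:.2f}"
                )
        regions = None
        if rec.scaffold_id in tracks_by_scaffold:
            regions = []
            for t in tracks_by_scaffold[rec.scaffold_id]:
                if len(t.depth) < config.anomaly_window_bp or np.median(t.depth) == 0:
                    continue
                regions += detect_anomalous_regions(
                    t,
                    window_bp=config.anomaly_window_bp,
                    step_bp=config.anomaly_step_bp,
                    high_fold=config.anomaly_high_fold,
                    low_fold=config.anomaly_low_fold,
                    min_region_bp=config.anomaly_min_region_bp,
                )
            if regions:
                evidence.append(f"misassembly: {len(regions)} anomalous region(s)")
        esom_v = esom_verdicts.get(rec.scaffold_id)
        if esom_v is not None and not esom_v.co_binned:
            evidence.append(
                f"esom: only {esom_v.fraction_in_territory:.2f} of fragments in "
                f"bin territory"
            )
        # Misassembly regions indicate local assembly problems, not wrong bin
        # membership; they flag the scaffold all the same.
        verdict = "flagged" if evidence else "supported"
        scaffolds.append(
            ScaffoldVerdict(
                scaffold_id=rec.scaffold_id,
                composition=comp,
                coverage=cov,
                misassembly_regions=regions,
                esom=esom_v,
                verdict=verdict,
                evidence=evidence,
            )
        )
    return VerificationReport(
        bin_id=bin_id, scaffolds=scaffolds, skipped_stages=skipped, config=config
    )


def verify_all_bins(
    bins: Mapping[str, Sequence[ScaffoldRecord]],
    coverage: CoverageMatrix | None = None,
    depth_tracks: Sequence[DepthTrack] | None = None,
    config: RunConfig | None = None,
    run_esom: bool = True,
) -> dict[str, VerificationReport]:
    """Verify every bin, sharing a single community-wide ESOM training."""
    config = config or RunConfig()
    som = train_community_som(bins, config) if run_esom else None
    tracks_by_scaffold: dict[str, list[DepthTrack]] = {}
    for t in depth_tracks or []:
        tracks_by_scaffold.setdefault(t.scaffold_id, []).append(t)
    reports = {}
    for bin_id in sorted(bins):
        bin_tracks = (
            [
                t
                for r in bins[bin_id]
                for t in tracks_by_scaffold.get(r.scaffold_id, [])
            ]
            if depth_tracks is not None
            else None
        )
        reports[bin_id] = verify_bin(
            bin_id,
            bins,
            coverage=coverage,
            depth_tracks=bin_tracks,
            config=config,
            run_esom=run_esom,
            som=som,
        )
    return reports
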