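"""End-to-end orchestration: FASTQ -> reports, reproducible from one config.

Stages per locus: merge read pairs, expected-error filter, dereplicate per
sample, pool across samples, cluster MOTUs at 99% identity, classify each
MOTU centroid, tally the community matrix, verify every sample against its
label at species/genus/family, summarize by source type and dosage form,
flag authenticity, and ordinate (CLR + PCA).  Identical seed and inputs
give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import motu as _motu
from . import ordination as _ordination
from . import preprocess as _pre
from . import verify as _verify
from .labels import FormulationLabel, read_label_manifest
from .simulate import read_fastq_pairs
from .taxonomy import (
    build_reference_index,
    load_reference,
    species_lineage_map,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run (fully serializable)."""

    refdb_fasta: str
    taxonomy_tsv: str
    labels_tsv: str
    fastq_dir: str
    out_dir: str
    seed: int = 0
    loci: tuple[str, ...] = ("ITS2", "RBCL")
    k: int = 8
    min_overlap: int = 30
    max_mismatch_frac: float = 0.1
    max_ee: float = 1.0
    min_len: int = 150
    max_len: int = 600
    motu_threshold: float = 0.99
    n_boot: int = 100
    conf_cutoff: float = 0.8
    species_identity: float = 0.99
    species_coverage: float = 0.9
    min_reads: int = 5
    ranks: tuple[str, ...] = ("species", "genus", "family")
    ordination_min_total: int = 10
    pseudocount: float = 1.0

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["loci"] = list(self.loci)
        payload["ranks"] = list(self.ranks)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["loci"] = tuple(payload.get("loci", ("ITS2", "RBCL")))
        payload["ranks"] = tuple(payload.get("ranks", ("species", "genus", "family")))
        return cls(**payload)


def _fmt_pct(x: float) -> str:
    return f"{x:.2f}"


@dataclass
class LocusResult:
    matrix: _motu.CommunityMatrix
    records: list[_verify.VerificationRecord]
    stage_counts: pd.DataFrame
    classifications: dict[str, _classify.Classification]


def _process_locus(config: RunConfig, locus: str, labels: list[FormulationLabel],
                   index, lineage_map, seed: int) -> LocusResult:
    fastq_dir = Path(config.fastq_dir)
    per_sample_uniques: dict[str, list[_pre.UniqueSeq]] = {}
    stage_rows = []
    for label in sorted(labels, key=lambda l: l.sample_id):
        sid = label.sample_id
        r1 = fastq_dir / f"{sid}_{locus}_R1.fastq"
        r2 = fastq_dir / f"{sid}_{locus}_R2.fastq"
        if not r1.exists() or not r2.exists():
            raise FileNotFoundError(f"stage merge failed for sample {sid}: missing {r1} or {r2}")
        pairs = read_fastq_pairs(r1, r2)
        merged = []
        for pair in pairs:
            m = _pre.merge_pair(pair, config.min_overlap, config.max_mismatch_frac)
            if m is not _pre.REJECT:
                merged.append(m)
        kept, _rejected = _pre.quality_filter(
            merged, config.max_ee, config.min_len, config.max_len
        )
        uniques = _pre.dereplicate(kept)
        per_sample_uniques[sid] = uniques
        stage_rows.append(
            dict(sample_id=sid, locus=locus, raw=len(pairs), merged=len(merged),
                 filtered=len(kept), unique=len(uniques))
        )
        log.info("%s %s: raw=%d merged=%d filtered=%d unique=%d",
                 sid, locus, len(pairs), len(merged), len(kept), len(uniques))
    pooled = _motu.pool_sample_uniques(per_sample_uniques)
    motus = _motu.cluster_motus(pooled, threshold=config.motu_threshold)
    rng = np.random.default_rng(seed)
    classifications = {}
    for motu in motus:  # motus are in deterministic order
        cls_seed = int(rng.integers(0, 2**31 - 1))
        classifications[motu.motu_id] = _classify.classify_sequence(
            motu.centroid, index,
            n_boot=config.n_boot, conf_cutoff=config.conf_cutoff,
            rng_seed=cls_seed, query_id=motu.motu_id,
            species_threshold=config.species_identity,
            species_min_coverage=config.species_coverage,
        )
    matrix = _motu.tally_assignments(
        motus, classifications, [l.sample_id for l in labels]
    )
    records: list[_verify.VerificationRecord] = []
    for label in sorted(labels, key=lambda l: l.sample_id):
        records.extend(
            _verify.verify_sample(
                label, matrix, locus, lineage_map,
                ranks=config.ranks, min_reads=config.min_reads,
            )
        )
    return LocusResult(matrix, records, pd.DataFrame(stage_rows), classifications)


def _write_verification(records, path: Path) -> None:
    with path.open("w") as fh:
        fh.write(
            "sample_id\tlocus\trank\tn_listed\tn_identified\tn_not_identified\t"
            "pct_identified_absolute\tpct_not_identified_relative\t"
            "identified_taxa\tnot_identified_taxa\tother_detected_taxa\n"
        )
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.locus}\t{r.rank}\t{r.n_listed}\t"
                f"{r.n_identified}\t{r.n_not_identified}\t"
                f"{_fmt_pct(r.pct_identified_absolute)}\t"
                f"{_fmt_pct(r.pct_not_identified_relative)}\t"
                f"{';'.join(sorted(r.identified_taxa))}\t"
                f"{';'.join(sorted(r.not_identified_taxa))}\t"
                f"{';'.join(sorted(r.other_detected_taxa))}\n"
            )


def _write_summaries(records, labels_by_sample, rank: str, out: Path, locus: str) -> None:
    rank_records = [r for r in records if r.rank == rank]
    if not rank_records:
        return
    for group_by, fname in (
        ("source_type", f"summary_source_{rank}_{locus}.tsv"),
        ("dosage_form", f"summary_dosage_{rank}_{locus}.tsv"),
    ):
        summaries = _verify.summarize(rank_records, labels_by_sample, group_by)
        with (out / fname).open("w") as fh:
            fh.write(
                "group\tlocus\trank\tn_samples\tn_listed\tn_identified\t"
                "n_not_identified\tpct_identified_absolute\tpct_not_identified_relative\n"
            )
            for s in summaries:
                fh.write(
                    f"{s.group}\t{s.locus}\t{s.rank}\t{s.n_samples}\t{s.n_listed}\t"
                    f"{s.n_identified}\t{s.n_not_identified}\t"
                    f"{_fmt_pct(s.pct_identified_absolute)}\t"
                    f"{_fmt_pct(s.pct_not_identified_relative)}\n"
                )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Any stage failure aborts with the failing sample and stage named; the
    effective config is echoed into the output directory so the run is
    reproducible from it alone.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    records = load_reference(config.refdb_fasta, config.taxonomy_tsv)
    lineage_map = species_lineage_map(records)
    labels = read_label_manifest(config.labels_tsv)
    labels_by_sample = {l.sample_id: l for l in labels}
    seed_root = np.random.SeedSequence(config.seed)
    locus_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seed_root.spawn(len(config.loci))]
    all_stage_counts = []
    exclusions = []
    authenticity_rows = []
    for locus, locus_seed in zip(config.loci, locus_seeds):
        locus_records = [r for r in records if r.locus == locus]
        if not locus_records:
            raise ValueError(f"no reference records for locus {locus}")
        index = build_reference_index(locus_records, k=config.k)
        result = _process_locus(config, locus, labels, index, lineage_map, locus_seed)
        all_stage_counts.append(result.stage_counts)
        result.matrix.to_tsv(out / f"matrix_{locus}.tsv", out / f"lineages_{locus}.tsv")
        _write_verification(result.records, out / f"verification_{locus}.tsv")
        for rank in config.ranks:
            _write_summaries(result.records, labels_by_sample, rank, out, locus)
        with (out / f"classifications_{locus}.tsv").open("w") as fh:
            fh.write("motu_id\taccepted_rank\tlabel_path\tspecies_identity\tbest_record_id\n")
            for motu_id in sorted(result.classifications):
                c = result.classifications[motu_id]
                fh.write(
                    f"{motu_id}\t{c.accepted_rank or 'NONE'}\t{c.label_path()}\t"
                    f"{c.species_identity:.4f}\t{c.best_record_id or ''}\n"
                )
        for sid in sorted(result.matrix.no_motu):
            exclusions.append((sid, locus, "NO_MOTU"))
        by_sample: dict[str, list] = {}
        for r in result.records:
            by_sample.setdefault(r.sample_id, []).append(r)
        for sid in sorted(by_sample):
            authenticity_rows.append(
                (sid, locus, _verify.authenticity_flag(by_sample[sid]))
            )
        # ordination on the species-level rows
        sp_rows = [
            taxon for taxon, lin in result.matrix.lineages.items()
            if lin.species != "UNKNOWN"
        ]
        counts = result.matrix.counts.loc[sorted(sp_rows)]
        active = [c for c in counts.columns if c not in result.matrix.no_motu]
        counts = counts[active]
        try:
            ordn = _ordination.ordinate(
                counts, min_total=config.ordination_min_total,
                pseudocount=config.pseudocount,
            )
        except ValueError as exc:
            log.warning("ordination skipped for %s: %s", locus, exc)
        else:
            ordn.scores.round(6).to_csv(out / f"pca_scores_{locus}.tsv", sep="\t",
                                        index_label="sample_id")
            pd.DataFrame(
                {"axis": ordn.scores.columns,
                 "variance_fraction": np.round(ordn.variance_fractions, 6)}
            ).to_csv(out / f"pca_variance_{locus}.tsv", sep="\t", index=False)
    pd.concat(all_stage_counts, ignore_index=True).to_csv(
        out / "stage_counts.tsv", sep="\t", index=False
    )
    with (out / "exclusions.tsv").open("w") as fh:
        fh.write("sample_id\tlocus\treason\n")
        for sid, locus, reason in exclusions:
            fh.write(f"{sid}\t{locus}\t{reason}\n")
    with (out / "authenticity.tsv").open("w") as fh:
        fh.write("sample_id\tlocus\tauthentic\n")
        for sid, locus, flag in authenticity_rows:
            fh.write(f"{sid}\t{locus}\t{str(flag).lower()}\n")
    return out
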