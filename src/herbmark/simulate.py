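"""Synthetic study generator: reference database, formulations, reads.

Everything downstream of sequencing can be exercised without any download:
this module builds a hierarchically structured reference marker database
(family/genus/species sequence divergence at two loci), draws polyherbal
formulations with processing dropout, undeclared plant admixture and fungal
contamination, and emits 300-bp paired-end reads with a linear substitution
error ramp, Phred qualities derived from the true error rates, and spliced
chimeras.  The ground truth of every sample is retained so recovery can be
scored exactly.

All randomness flows through one seeded numpy Generator; identical seeds
give byte-identical FASTQ output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .labels import FormulationLabel
from .preprocess import PHRED_OFFSET, revcomp
from .taxonomy import Lineage, RefRecord

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_READ_LEN = 300
DEFAULT_ERR0 = 5e-4
DEFAULT_ERR1 = 5e-3
DEFAULT_CHIMERA_FRACTION = 0.01
DEFAULT_DROPOUT_RATE = 0.2
DEFAULT_ADMIXTURE_RATE = 0.15
DEFAULT_CONTAMINANT_PROB = 0.3
DEFAULT_ALPHA = 1.0
MAX_QUAL = 40


@dataclass(frozen=True)
class GroundTruth:
    """True composition of one synthetic product."""

    sample_id: str
    abundances: Mapping[str, float]  # species -> relative abundance (sums to 1)
    present_declared: tuple[str, ...]
    dropped_declared: tuple[str, ...]
    admixture_taxa: tuple[str, ...]
    contaminant_taxa: tuple[str, ...]
    chimera_fraction: float = DEFAULT_CHIMERA_FRACTION

    def __post_init__(self) -> None:
        if self.abundances:
            total = float(sum(self.abundances.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances sum to {total}, expected 1")
        if set(self.dropped_declared) & set(self.present_declared):
            raise ValueError("dropped and present declared sets overlap")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    fwd_seq: str
    fwd_qual: str
    rev_seq: str
    rev_qual: str
    true_source: str = ""  # record_id, or CHIMERA:<id1>|<id2>:<breakpoint>

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


# ---------------------------------------------------------------------------
# Reference database generation

def _alpha_id(i: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa', ..."""
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def random_seq(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability *rate*."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    if mask.any():
        shifts = rng.integers(1, 4, size=int(mask.sum()))
        idx = ((np.searchsorted(_BASES, arr[mask]) + shifts) % 4).astype(np.intp)
        arr[mask] = _BASES[idx]
    return arr.tobytes().decode("ascii")


def simulate_reference_db(
    rng: np.random.Generator,
    n_families: int = 15,
    genera_per_family: int = 2,
    species_per_genus: int = 2,
    n_fungi: int = 3,
    loci: Sequence[str] = ("ITS2", "RBCL"),
    len_range: tuple[int, int] = (400, 480),
    genus_divergence: float = 0.08,
    species_divergence: float = 0.04,
) -> list[RefRecord]:
    """Hierarchically diverged reference records at each locus.

    Congeneric species differ by ~2x ``species_divergence`` (default ~8%,
    well below the 99% species-acceptance band), genera within a family by
    ~2x ``genus_divergence``.  Fungal contaminant references carry a
    non-plant kingdom so downstream reports can flag them.
    """
    records: list[RefRecord] = []
    for fi in range(n_families):
        stem = _alpha_id(fi).capitalize()
        family = f"{stem}aceae"
        lineage_head = dict(
            kingdom="Plantae", phylum="Tracheophyta", class_="Magnoliopsida",
            order=f"{stem}ales", family=family,
        )
        roots = {locus: random_seq(int(rng.integers(*len_range)), rng) for locus in loci}
        for gi in range(genera_per_family):
            genus = f"{stem}genus{_alpha_id(gi)}"
            genus_seqs = {loc: mutate(s, genus_divergence, rng) for loc, s in roots.items()}
            for si in range(species_per_genus):
                species = f"{genus} {_alpha_id(si)}ensis"
                lineage = Lineage(**lineage_head, genus=genus, species=species)
                for locus in loci:
                    seq = mutate(genus_seqs[locus], species_divergence, rng)
                    rid = f"{locus}_{genus}_{_alpha_id(si)}ensis"
                    records.append(RefRecord(rid, locus, seq, lineage))
    for ci in range(n_fungi):
        stem = _alpha_id(ci).capitalize()
        genus = f"Fung{stem.lower()}us"
        species = f"{genus} contaminans"
        lineage = Lineage(
            kingdom="Fungi", phylum="Ascomycota", class_="Sordariomycetes",
            order="Hypocreales", family=f"Fung{stem.lower()}aceae",
            genus=genus, species=species,
        )
        for locus in loci:
            seq = random_seq(int(rng.integers(*len_range)), rng)
            records.append(RefRecord(f"{locus}_{genus}_contaminans", locus, seq, lineage))
    return records


def plant_species_pool(records: Iterable[RefRecord]) -> list[str]:
    return sorted({r.lineage.species for r in records if r.lineage.kingdom == "Plantae"})


def fungal_species_pool(records: Iterable[RefRecord]) -> list[str]:
    return sorted({r.lineage.species for r in records if r.lineage.kingdom == "Fungi"})


# ---------------------------------------------------------------------------
# Formulations

def simulate_formulation(
    n_species: int,
    pool: Sequence[str],
    rng: np.random.Generator,
    dropout_rate: float = DEFAULT_DROPOUT_RATE,
    admixture_rate: float = DEFAULT_ADMIXTURE_RATE,
    contaminant_pool: Sequence[str] = (),
    contaminant_prob: float = DEFAULT_CONTAMINANT_PROB,
    alpha: float | None = DEFAULT_ALPHA,
    chimera_fraction: float = DEFAULT_CHIMERA_FRACTION,
    sample_id: str = "S1",
    product_name: str = "",
    source_type: str = "IN_HOUSE",
    dosage_form: str = "POWDER",
) -> tuple[FormulationLabel, GroundTruth]:
    """Draw one product label and its ground-truth composition.

    Each declared species is dropped independently with ``dropout_rate``
    (processing degradation); undeclared plant admixture is added at
    ``admixture_rate`` per declared species; fungal contamination occurs
    with probability ``contaminant_prob`` (1-2 taxa).  Abundances over the
    present taxa are symmetric-Dirichlet(``alpha``); ``alpha=None`` means
    exactly uniform.
    """
    if not 1 <= n_species <= 55:
        raise ValueError("n_species must be in [1, 55]")
    if n_species > len(pool):
        raise ValueError(f"n_species={n_species} exceeds pool size {len(pool)}")
    declared = sorted(rng.choice(np.asarray(pool, dtype=object), size=n_species, replace=False))
    keep_mask = rng.random(n_species) >= dropout_rate
    present_declared = tuple(s for s, keep in zip(declared, keep_mask) if keep)
    dropped = tuple(s for s, keep in zip(declared, keep_mask) if not keep)
    remaining = [s for s in pool if s not in set(declared)]
    n_admix = min(int(rng.binomial(n_species, admixture_rate)), len(remaining))
    admixture = tuple(
        sorted(rng.choice(np.asarray(remaining, dtype=object), size=n_admix, replace=False))
    ) if n_admix else ()
    contaminants: tuple[str, ...] = ()
    if contaminant_pool and rng.random() < contaminant_prob:
        n_cont = min(int(rng.integers(1, 3)), len(contaminant_pool))
        contaminants = tuple(
            sorted(rng.choice(np.asarray(contaminant_pool, dtype=object), size=n_cont, replace=False))
        )
    present = list(present_declared) + list(admixture) + list(contaminants)
    if present:
        if alpha is None:
            weights = np.full(len(present), 1.0 / len(present))
        else:
            weights = rng.dirichlet([alpha] * len(present))
        abundances = {taxon: float(w) for taxon, w in zip(present, weights)}
        # exact renormalization guards the 1e-9 sum invariant
        total = sum(abundances.values())
        abundances = {t: w / total for t, w in abundances.items()}
    else:
        abundances = {}
    label = FormulationLabel(
        sample_id=sample_id,
        product_name=product_name or f"Product {sample_id}",
        source_type=source_type,
        dosage_form=dosage_form,
        declared_species=tuple(declared),
    )
    truth = GroundTruth(
        sample_id=sample_id,
        abundances=abundances,
        present_declared=present_declared,
        dropped_declared=dropped,
        admixture_taxa=admixture,
        contaminant_taxa=contaminants,
        chimera_fraction=chimera_fraction,
    )
    return label, truth


# ---------------------------------------------------------------------------
# Reads

def _phred_string(p: np.ndarray) -> str:
    with np.errstate(divide="ignore"):
        q = np.where(p > 0, -10.0 * np.log10(np.maximum(p, 1e-300)), float(MAX_QUAL))
    q = np.minimum(np.floor(q + 0.5), MAX_QUAL).astype(np.uint8)
    return (q + PHRED_OFFSET).tobytes().decode("ascii")


def _apply_errors(seq: str, p: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < p[: arr.size]
    if mask.any():
        shifts = rng.integers(1, 4, size=int(mask.sum()))
        idx = ((np.searchsorted(_BASES, arr[mask]) + shifts) % 4).astype(np.intp)
        arr[mask] = _BASES[idx]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    truth: GroundTruth,
    records: Sequence[RefRecord],
    depth: int,
    rng: np.random.Generator,
    read_len: int = DEFAULT_READ_LEN,
    err0: float = DEFAULT_ERR0,
    err1: float = DEFAULT_ERR1,
    chimera_fraction: float | None = None,
    required_overlap: int = 30,
) -> list[ReadPair]:
    """Emit *depth* paired 300-bp-style reads for one sample at one locus.

    Reads are drawn from taxa proportional to their true abundance; the
    per-base substitution probability ramps linearly from ``err0`` at the
    read start to ``err1`` at the read end, and qualities encode the true
    rates (capped at Q40).  Chimeras splice two parent amplicons at a
    uniform breakpoint.  Amplicons leaving less than ``required_overlap``
    nt of mate overlap are skipped with a warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if chimera_fraction is None:
        chimera_fraction = truth.chimera_fraction
    by_species: dict[str, list[RefRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.lineage.species, []).append(rec)
    usable: dict[str, list[RefRecord]] = {}
    for taxon in truth.abundances:
        recs = by_species.get(taxon)
        if not recs:
            raise ValueError(f"no reference record at this locus for taxon {taxon!r}")
        kept = []
        for rec in recs:
            if len(rec.sequence) > 2 * read_len - required_overlap:
                log.warning(
                    "amplicon %s leaves <%d nt mate overlap, skipped",
                    rec.record_id, required_overlap,
                )
                continue
            kept.append(rec)
        if not kept:
            raise ValueError(f"no usable amplicon for taxon {taxon!r}")
        usable[taxon] = sorted(kept, key=lambda r: r.record_id)
    taxa = sorted(truth.abundances)
    probs = np.array([truth.abundances[t] for t in taxa])
    probs = probs / probs.sum()
    p_profile = (
        np.linspace(err0, err1, read_len) if read_len > 1 else np.array([err0])
    )
    qual_full = _phred_string(p_profile)
    pairs: list[ReadPair] = []
    for i in range(depth):
        if chimera_fraction > 0 and rng.random() < chimera_fraction:
            t1, t2 = (taxa[int(j)] for j in rng.choice(len(taxa), size=2, p=probs))
            r1 = usable[t1][int(rng.integers(len(usable[t1])))]
            r2 = usable[t2][int(rng.integers(len(usable[t2])))]
            lo = min(len(r1.sequence), len(r2.sequence))
            bp = int(rng.integers(1, lo))
            template = r1.sequence[:bp] + r2.sequence[bp:]
            source = f"CHIMERA:{r1.record_id}|{r2.record_id}:{bp}"
        else:
            taxon = taxa[int(rng.choice(len(taxa), p=probs))]
            rec = usable[taxon][int(rng.integers(len(usable[taxon])))]
            template = rec.sequence
            source = rec.record_id
        fwd_t = template[:read_len]
        rev_t = revcomp(template[-read_len:])
        fwd = _apply_errors(fwd_t, p_profile, rng)
        rev = _apply_errors(rev_t, p_profile, rng)
        pairs.append(
            ReadPair(
                read_id=f"{truth.sample_id}:{i:06d}",
                fwd_seq=fwd,
                fwd_qual=qual_full[: len(fwd)],
                rev_seq=rev,
                rev_qual=qual_full[: len(rev)],
                true_source=source,
            )
        )
    return pairs


def emit_fastq(
    pairs: Sequence[ReadPair],
    r1_path: str | Path,
    r2_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write R1/R2 FASTQ (4 lines per record, same ordering) and optionally
    a read-level truth manifest TSV."""
    with Path(r1_path).open("w") as f1, Path(r2_path).open("w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.fwd_seq}\n+\n{p.fwd_qual}\n")
            f2.write(f"@{p.read_id}/2\n{p.rev_seq}\n+\n{p.rev_qual}\n")
    if truth_path is not None:
        with Path(truth_path).open("w") as fh:
            fh.write("read_id\ttrue_source\n")
            for p in pairs:
                fh.write(f"{p.read_id}\t{p.true_source}\n")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Read paired FASTQ back into ReadPair objects (truth not recovered)."""

    def _read(path: Path) -> list[tuple[str, str, str]]:
        out = []
        lines = path.read_text().splitlines()
        if len(lines) % 4:
            raise ValueError(f"{path}: FASTQ line count not a multiple of 4")
        for i in range(0, len(lines), 4):
            header = lines[i]
            if not header.startswith("@"):
                raise ValueError(f"{path}: bad FASTQ header at line {i + 1}")
            out.append((header[1:].split("/")[0].split()[0], lines[i + 1], lines[i + 3]))
        return out

    fwd = _read(Path(r1_path))
    rev = _read(Path(r2_path))
    if len(fwd) != len(rev):
        raise ValueError("R1/R2 read counts differ")
    pairs = []
    for (fid, fseq, fqual), (rid, rseq, rqual) in zip(fwd, rev):
        if fid != rid:
            raise ValueError(f"read ordering mismatch: {fid} vs {rid}")
        pairs.append(ReadPair(fid, fseq, fqual, rseq, rqual))
    return pairs


# ---------------------------------------------------------------------------
# Whole-study scenarios

#: Declared species count per product in the audited 39-product panel.
PANEL_SPECIES_COUNTS = (
    48, 48, 49, 55, 17, 22, 27, 19, 30, 9, 12, 7, 6, 16, 26, 13, 25, 18, 12,
    9, 11, 21, 9, 12, 12, 8, 6, 4, 30, 4, 5, 1, 1, 4, 7, 7, 3, 1, 5,
)
#: Dosage form per product (24 in-house powders; registered products 25-39
#: comprise 1 powder, 9 capsules and 5 tablets).
PANEL_DOSAGE_FORMS = ("POWDER",) * 24 + (
    "CAPSULE", "CAPSULE", "POWDER", "CAPSULE", "CAPSULE", "CAPSULE",
    "CAPSULE", "CAPSULE", "CAPSULE", "TABLET", "TABLET", "TABLET",
    "CAPSULE", "TABLET", "TABLET",
)


@dataclass(frozen=True)
class ProductSpec:
    sample_id: str
    n_species: int
    source_type: str
    dosage_form: str
    depth: int


@dataclass(frozen=True)
class Scenario:
    """A full synthetic study: product roster plus generator parameters."""

    products: tuple[ProductSpec, ...]
    loci: tuple[str, ...] = ("ITS2", "RBCL")
    dropout_rate: float = DEFAULT_DROPOUT_RATE
    admixture_rate: float = DEFAULT_ADMIXTURE_RATE
    contaminant_prob: float = DEFAULT_CONTAMINANT_PROB
    alpha: float | None = DEFAULT_ALPHA
    chimera_fraction: float = DEFAULT_CHIMERA_FRACTION
    err0: float = DEFAULT_ERR0
    err1: float = DEFAULT_ERR1
    read_len: int = DEFAULT_READ_LEN
    n_families: int = 15
    genera_per_family: int = 2
    species_per_genus: int = 2
    n_fungi: int = 3
    zero_depth_samples: tuple[str, ...] = ()


def default_scenario(depth_per_species: int = 40, min_depth: int = 200) -> Scenario:
    """The audited panel's shape: 39 products, 24 in-house / 15 registered,
    25 powders / 5 tablets / 9 capsules, declared lists of 1-55 species.

    Depth scales with label size so every declared species has ample read
    support at desk scale.
    """
    products = tuple(
        ProductSpec(
            sample_id=f"S{i + 1:02d}",
            n_species=n,
            source_type="IN_HOUSE" if i < 24 else "REGISTERED",
            dosage_form=PANEL_DOSAGE_FORMS[i],
            depth=max(min_depth, depth_per_species * n),
        )
        for i, n in enumerate(PANEL_SPECIES_COUNTS)
    )
    return Scenario(products=products)


@dataclass
class StudyBundle:
    """Everything one simulated study produced, in memory."""

    records: list[RefRecord]
    labels: list[FormulationLabel]
    truths: dict[str, GroundTruth]
    reads: dict[tuple[str, str], list[ReadPair]]  # (sample_id, locus) -> pairs
    scenario: Scenario


def simulate_study(scenario: Scenario, seed: int) -> StudyBundle:
    """Run the whole generator for a scenario under one master seed."""
    master = np.random.default_rng(seed)
    db_rng, form_rng, read_rng = (
        np.random.default_rng(s) for s in master.integers(0, 2**31 - 1, size=3)
    )
    records = simulate_reference_db(
        db_rng,
        n_families=scenario.n_families,
        genera_per_family=scenario.genera_per_family,
        species_per_genus=scenario.species_per_genus,
        n_fungi=scenario.n_fungi,
        loci=scenario.loci,
    )
    pool = plant_species_pool(records)
    contaminant_pool = fungal_species_pool(records)
    labels: list[FormulationLabel] = []
    truths: dict[str, GroundTruth] = {}
    reads: dict[tuple[str, str], list[ReadPair]] = {}
    for spec in scenario.products:
        label, truth = simulate_formulation(
            spec.n_species,
            pool,
            form_rng,
            dropout_rate=scenario.dropout_rate,
            admixture_rate=scenario.admixture_rate,
            contaminant_pool=contaminant_pool,
            contaminant_prob=scenario.contaminant_prob,
            alpha=scenario.alpha,
            chimera_fraction=scenario.chimera_fraction,
            sample_id=spec.sample_id,
            source_type=spec.source_type,
            dosage_form=spec.dosage_form,
        )
        labels.append(label)
        truths[spec.sample_id] = truth
        for locus in scenario.loci:
            if spec.sample_id in scenario.zero_depth_samples or not truth.abundances:
                reads[(spec.sample_id, locus)] = []
                continue
            locus_records = [r for r in records if r.locus == locus]
            reads[(spec.sample_id, locus)] = simulate_reads(
                truth,
                locus_records,
                depth=spec.depth,
                rng=read_rng,
                read_len=scenario.read_len,
                err0=scenario.err0,
                err1=scenario.err1,
                chimera_fraction=scenario.chimera_fraction,
            )
    return StudyBundle(records, labels, truths, reads, scenario)


def write_study(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Write the study to disk: reference FASTA + taxonomy TSV, label
    manifest, per-sample/locus paired FASTQ and truth manifests."""
    from .labels import write_label_manifest
    from .taxonomy import write_reference_fasta, write_taxonomy_table

    out = Path(out_dir)
    (out / "fastq").mkdir(parents=True, exist_ok=True)
    write_reference_fasta(bundle.records, out / "refdb.fasta")
    write_taxonomy_table(
        [(r.record_id, r.lineage) for r in bundle.records], out / "taxonomy.tsv"
    )
    write_label_manifest(bundle.labels, out / "labels.tsv")
    with (out / "ground_truth.tsv").open("w") as fh:
        fh.write(
            "sample_id\tpresent_declared\tdropped_declared\tadmixture_taxa\t"
            "contaminant_taxa\tabundances\n"
        )
        for sample_id in sorted(bundle.truths):
            t = bundle.truths[sample_id]
            ab = ",".join(f"{k}:{v:.6g}" for k, v in sorted(t.abundances.items()))
            fh.write(
                f"{sample_id}\t{';'.join(t.present_declared)}\t"
                f"{';'.join(t.dropped_declared)}\t{';'.join(t.admixture_taxa)}\t"
                f"{';'.join(t.contaminant_taxa)}\t{ab}\n"
            )
    for (sample_id, locus), pairs in sorted(bundle.reads.items()):
        base = out / "fastq" / f"{sample_id}_{locus}"
        emit_fastq(
            pairs,
            f"{base}_R1.fastq",
            f"{base}_R2.fastq",
            truth_path=f"{base}_truth.tsv",
        )
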