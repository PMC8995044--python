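"""Synthetic data generator with planted methylation classes and
transcript-integrity effects.

Emits a complete, file-level input bundle — GFF3 annotation, Bismark-style
cytosine report, long-read BED12, short-read BED, plus a truth table — so
every pipeline stage can be exercised and verified without external data.

What it emulates
----------------
* Multi-exon genes laid out non-overlapping on synthetic chromosomes,
  alternating strands.
* Per-gene methylation class (gbM / UM / teM) with context-specific
  site-level methylation rates; per-site coverage is Poisson and methylated
  read counts are binomial, with a bisulfite non-conversion floor.
* Full-length long reads: antisense with a class-dependent probability;
  sense reads start at the annotated TSS (conventional) or at a uniform
  internal position 3' of exon-1 start; introns are retained independently
  with a per-intron rate calibrated so the read-level probability of
  retaining at least one intron equals the planted per-class value.
* Short reads: uniform exonic background coverage, an internal-initiation
  component that elevates coverage 3' of sampled internal start points in
  proportion to the class's internal-start rate, and intron reads in
  proportion to the class's retention rate.

Default effect sizes are the group means the pipeline is meant to detect:
conventional-TSS 0.81 (gbM) vs 0.78 (UM), antisense 0.0046 vs 0.016,
intron retention 0.149 vs 0.106.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel, load_annotation, write_gff3
from .intervals import GenomicInterval

CONTEXTS = ("CG", "CHG", "CHH")
_TRI = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters for one methylation class."""

    meth_rate: dict[str, float]
    p_conventional_tss: float
    p_antisense: float
    p_intron_retention: float  # read-level P(retain >=1 intron)

    @property
    def p_internal_start(self) -> float:
        return 1.0 - self.p_conventional_tss


def _default_class_params() -> dict[str, ClassParams]:
    err = 0.005
    return {
        "gbM": ClassParams(
            meth_rate={"CG": 0.70, "CHG": err, "CHH": err},
            p_conventional_tss=0.81,
            p_antisense=0.0046,
            p_intron_retention=0.149,
        ),
        "UM": ClassParams(
            meth_rate={"CG": err, "CHG": err, "CHH": err},
            p_conventional_tss=0.78,
            p_antisense=0.016,
            p_intron_retention=0.106,
        ),
        "teM": ClassParams(
            meth_rate={"CG": 0.80, "CHG": 0.70, "CHH": 0.40},
            p_conventional_tss=0.70,
            p_antisense=0.02,
            p_intron_retention=0.15,
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions the
    pipeline's planted-effect checks assume."""

    n_genes: int = 2000
    exon_count_range: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (80, 200)
    intergenic_gap: int = 300
    genes_per_chrom: int = 100
    class_priors: dict[str, float] = field(
        default_factory=lambda: {"gbM": 0.35, "UM": 0.55, "teM": 0.10}
    )
    class_params: dict[str, ClassParams] = field(default_factory=_default_class_params)
    error_rate: float = 0.005
    site_spacing: dict[str, int] = field(
        default_factory=lambda: {"CG": 25, "CHG": 25, "CHH": 12}
    )
    site_coverage_mean: float = 10.0
    reads_per_gene_mean: float = 20.0
    reads_per_gene_dispersion: float = 5.0  # NB shape; larger = closer to Poisson
    shortread_mean_reads_per_gene: float = 150.0
    shortread_read_length: int = 100
    # condition name -> optional per-class overrides:
    #   {"p_internal_by_class": {...}, "p_ir_by_class": {...}}
    shortread_conditions: dict[str, dict] = field(default_factory=lambda: {"WT": {}})

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        total = sum(self.class_priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class priors must sum to 1, got {total}")
        for name, cp in self.class_params.items():
            probs = [cp.p_conventional_tss, cp.p_antisense, cp.p_intron_retention]
            probs += list(cp.meth_rate.values())
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"class {name}: probability {p} outside [0,1]")
        if not 0.0 < self.error_rate < 1.0:
            raise ValueError("error_rate must be in (0,1)")
        for cond, overrides in self.shortread_conditions.items():
            for key in overrides:
                if key not in ("p_internal_by_class", "p_ir_by_class"):
                    raise ValueError(f"condition {cond}: unknown override {key}")
                for p in overrides[key].values():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"condition {cond}: probability {p} outside [0,1]")


def default_config() -> SimulationConfig:
    return SimulationConfig()


# ---------------------------------------------------------------- annotation


def _simulate_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    for i in range(cfg.n_genes):
        chrom = f"chr{i // cfg.genes_per_chrom + 1}"
        if i % cfg.genes_per_chrom == 0:
            cursor = cfg.intergenic_gap
        strand = "+" if i % 2 == 0 else "-"
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = rng.integers(
            cfg.exon_length_range[0], cfg.exon_length_range[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, size=n_exons - 1
        )
        exons = []
        pos = cursor
        for j in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[j]), strand))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        cursor = pos + cfg.intergenic_gap
        if strand == "-":
            exons.reverse()
        gid = f"G{i:05d}"
        span = GenomicInterval(
            chrom, min(e.start for e in exons), max(e.end for e in exons), strand
        )
        genes.append(GeneModel(gene_id=gid, span=span, exons=tuple(exons)))
    return genes


def _assign_classes(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[str]:
    names = sorted(cfg.class_priors)
    probs = [cfg.class_priors[n] for n in names]
    idx = rng.choice(len(names), size=cfg.n_genes, p=probs)
    return [names[i] for i in idx]


# --------------------------------------------------------------- methylation


def _simulate_cytosine_report(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    classes: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = {k: [] for k in ("chrom", "pos", "strand", "meth", "unmeth", "context")}
    for gene, cls in zip(genes, classes):
        params = cfg.class_params[cls]
        for ctx in CONTEXTS:
            spacing = cfg.site_spacing[ctx]
            positions = np.arange(gene.span.start, gene.span.end, spacing)
            if positions.size == 0:
                continue
            cov = rng.poisson(cfg.site_coverage_mean, size=positions.size)
            keep = cov > 0
            positions, cov = positions[keep], cov[keep]
            rate = max(params.meth_rate[ctx], cfg.error_rate)
            meth = rng.binomial(cov, rate)
            rows["chrom"].append(np.full(positions.size, gene.chrom, dtype=object))
            rows["pos"].append(positions)
            rows["strand"].append(np.full(positions.size, "+", dtype=object))
            rows["meth"].append(meth)
            rows["unmeth"].append(cov - meth)
            rows["context"].append(np.full(positions.size, ctx, dtype=object))
    df = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})
    df["tri"] = df["context"].map(_TRI)
    return df


def write_cytosine_report(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["pos"] = out["pos"] + 1  # 1-based on disk
    out[["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------- long reads


def per_intron_retention_rate(p_read_level: float, n_introns: int) -> float:
    """Per-intron independent retention rate q with
    1 - (1-q)^k == p_read_level, so the read-level marginal equals the
    planted per-class value for every intron count k."""
    if n_introns == 0 or p_read_level <= 0.0:
        return 0.0
    return 1.0 - (1.0 - p_read_level) ** (1.0 / n_introns)


def _read_blocks(
    gene: GeneModel, start_5p: int, retained: set[int]
) -> tuple[GenomicInterval, ...]:
    """Aligned blocks of a read starting at ``start_5p`` (gene orientation)
    running to the gene's 3' end.

    Exon parts inside the window are always covered; an intron is covered
    when retained, or from the read start onward when the read initiates
    inside it (its donor site lies upstream of the read, so the remainder
    cannot be spliced).
    """
    if gene.strand == "+":
        window = (start_5p, gene.span.end)
    else:
        window = (gene.span.start, start_5p + 1)
    segs: list[tuple[int, int]] = []
    for ex in gene.exons:
        s, e = max(ex.start, window[0]), min(ex.end, window[1])
        if s < e:
            segs.append((s, e))
    for idx, intron in enumerate(gene.introns, start=1):
        if idx in retained:
            s, e = max(intron.start, window[0]), min(intron.end, window[1])
            if s < e:
                segs.append((s, e))
        elif intron.contains_point(start_5p):
            if gene.strand == "+":
                segs.append((start_5p, intron.end))
            else:
                segs.append((intron.start, start_5p + 1))
    segs.sort()
    merged = [list(segs[0])]
    for s, e in segs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple(GenomicInterval(gene.chrom, s, e, gene.strand) for s, e in merged)


def _simulate_long_reads(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    classes: list[str],
    rng: np.random.Generator,
) -> tuple[list[tuple], list[int]]:
    """Returns (BED12 rows, realized read count per gene)."""
    rows = []
    realized = []
    shape = cfg.reads_per_gene_dispersion
    for gene, cls in zip(genes, classes):
        params = cfg.class_params[cls]
        lam = rng.gamma(shape, cfg.reads_per_gene_mean / shape)
        n_reads = int(rng.poisson(lam))
        realized.append(n_reads)
        # A read starting 3' of the last intron spans no intron and cannot
        # retain; calibrate the conditional retention probability so the
        # sense-read-level expectation equals the planted value exactly.
        p_adj = params.p_intron_retention
        if gene.introns:
            last = gene.introns[-1]  # 3'-most intron in gene orientation
            if gene.strand == "+":
                s_go = last.start - gene.span.start
            else:
                s_go = gene.span.end - last.end
            p_span = (
                params.p_conventional_tss
                + params.p_internal_start * s_go / (gene.length - 1)
            )
            if p_span > 0:
                p_adj = min(1.0, params.p_intron_retention / p_span)
        for r in range(n_reads):
            rid = f"{gene.gene_id}_r{r}"
            antisense = rng.random() < params.p_antisense
            if antisense:
                start_5p = gene.exon1_start_5p
                strand = "-" if gene.strand == "+" else "+"
            else:
                strand = gene.strand
                if rng.random() < params.p_conventional_tss:
                    start_5p = gene.exon1_start_5p
                else:
                    # internal start: uniform over gene body 3' of exon-1 start
                    offset = int(rng.integers(1, gene.length))
                    if gene.strand == "+":
                        start_5p = gene.span.start + offset
                    else:
                        start_5p = gene.span.end - 1 - offset
            # retention is sampled among the introns the read fully spans:
            # an intron truncated by the read start cannot be observed as
            # retained
            if gene.strand == "+":
                window = (start_5p, gene.span.end)
            else:
                window = (gene.span.start, start_5p + 1)
            spanned = [
                i + 1
                for i, intron in enumerate(gene.introns)
                if window[0] <= intron.start and intron.end <= window[1]
            ]
            q = per_intron_retention_rate(p_adj, len(spanned))
            retained = {i for i in spanned if rng.random() < q}
            blocks = _read_blocks(gene, start_5p, retained)
            if strand != gene.strand:
                blocks = tuple(
                    GenomicInterval(b.chrom, b.start, b.end, strand) for b in blocks
                )
            rows.append((gene.chrom, blocks, rid, strand))
    return rows, realized


def write_bed12(rows: list[tuple], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, blocks, name, strand in rows:
            start = blocks[0].start
            end = blocks[-1].end
            sizes = ",".join(str(len(b)) for b in blocks) + ","
            offs = ",".join(str(b.start - start) for b in blocks) + ","
            fh.write(
                f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{start}\t{end}\t0\t"
                f"{len(blocks)}\t{sizes}\t{offs}\n"
            )


# --------------------------------------------------------------- short reads


def _exonic_positions(gene: GeneModel, read_len: int) -> list[tuple[int, int]]:
    """Valid (start, length) windows fully inside each exon, chromosome order."""
    wins = []
    for ex in sorted(gene.exons, key=lambda e: e.start):
        L = min(read_len, len(ex))
        wins.append((ex.start, ex.end - L, L))
    return wins


def _sample_exonic_read(
    gene: GeneModel,
    rng: np.random.Generator,
    read_len: int,
    min_5p: int | None = None,
) -> tuple[int, int]:
    """Uniform read start over exonic windows, optionally restricted 3' of
    ``min_5p`` in gene orientation. Returns (start, length)."""
    wins = []
    for s, smax, L in _exonic_positions(gene, read_len):
        lo, hi = s, smax
        if min_5p is not None:
            if gene.strand == "+":
                lo = max(lo, min_5p)
            else:
                hi = min(hi, min_5p - L + 1)
        if lo <= hi:
            wins.append((lo, hi, L))
    if not wins:
        return -1, 0
    weights = np.array([hi - lo + 1 for lo, hi, _ in wins], dtype=float)
    w = int(rng.choice(len(wins), p=weights / weights.sum()))
    lo, hi, L = wins[w]
    return int(rng.integers(lo, hi + 1)), L


def _simulate_short_reads_condition(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    classes: list[str],
    rng: np.random.Generator,
    overrides: dict,
) -> list[tuple[str, int, int, str, str]]:
    p_internal_over = overrides.get("p_internal_by_class", {})
    p_ir_over = overrides.get("p_ir_by_class", {})
    L = cfg.shortread_read_length
    rows = []
    n_read = 0
    for gene, cls in zip(genes, classes):
        params = cfg.class_params[cls]
        p_internal = p_internal_over.get(cls, params.p_internal_start)
        p_ir = p_ir_over.get(cls, params.p_intron_retention)
        depth = cfg.shortread_mean_reads_per_gene
        # uniform exonic background
        for _ in range(int(rng.poisson(depth))):
            s, length = _sample_exonic_read(gene, rng, L)
            if length:
                rows.append((gene.chrom, s, s + length, f"s{n_read}", gene.strand))
                n_read += 1
        # internal-initiation component: each read gets its own internal
        # start point uniform 3' of exon-1 start, then lands uniformly in
        # the exonic space downstream of it
        for _ in range(int(rng.poisson(depth * p_internal))):
            offset = int(rng.integers(1, gene.length))
            if gene.strand == "+":
                site = gene.span.start + offset
            else:
                site = gene.span.end - 1 - offset
            s, length = _sample_exonic_read(gene, rng, L, min_5p=site)
            if length:
                rows.append((gene.chrom, s, s + length, f"s{n_read}", gene.strand))
                n_read += 1
        # intron-retention component: reads inside introns
        introns = gene.introns
        if introns and p_ir > 0:
            ilens = np.array([len(i) for i in introns], dtype=float)
            for _ in range(int(rng.poisson(depth * p_ir))):
                w = int(rng.choice(len(introns), p=ilens / ilens.sum()))
                intr = introns[w]
                length = min(L, len(intr))
                s = int(rng.integers(intr.start, intr.end - length + 1))
                rows.append((gene.chrom, s, s + length, f"s{n_read}", gene.strand))
                n_read += 1
    return rows


def write_bed(rows: list[tuple], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


# -------------------------------------------------------------------- bundle


def simulate_dataset(config: SimulationConfig, seed: int, outdir: str) -> dict:
    """Write the full synthetic bundle into ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``) with file
    paths, library sizes, the seed and a config echo. Fully reproducible:
    identical (config, seed) yield byte-identical files.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = _simulate_genes(config, rng)
    classes = _assign_classes(config, rng)

    ann_path = os.path.join(outdir, "annotation.gff3")
    with open(ann_path, "w") as fh:
        write_gff3(AnnotationSet(genes), fh)

    cyt = _simulate_cytosine_report(config, genes, classes, rng)
    cyt_path = os.path.join(outdir, "cytosine_report.tsv")
    write_cytosine_report(cyt, cyt_path)

    lr_rows, realized = _simulate_long_reads(config, genes, classes, rng)
    lr_path = os.path.join(outdir, "longreads.bed12")
    write_bed12(lr_rows, lr_path)

    sr_paths = {}
    sr_sizes = {}
    for cond in sorted(config.shortread_conditions):
        overrides = config.shortread_conditions[cond]
        sr_rows = _simulate_short_reads_condition(config, genes, classes, rng, overrides)
        p = os.path.join(outdir, f"shortreads_{cond}.bed")
        write_bed(sr_rows, p)
        sr_paths[cond] = p
        sr_sizes[cond] = len(sr_rows)

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "class_label": classes,
            "p_conventional_tss": [
                config.class_params[c].p_conventional_tss for c in classes
            ],
            "p_antisense": [config.class_params[c].p_antisense for c in classes],
            "p_intron_retention": [
                config.class_params[c].p_intron_retention for c in classes
            ],
            "p_internal_start": [
                config.class_params[c].p_internal_start for c in classes
            ],
            "n_reads": realized,
        }
    )
    truth_path = os.path.join(outdir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)

    manifest = {
        "seed": seed,
        "n_genes": config.n_genes,
        # file names are relative to the bundle directory so that two
        # bundles from the same (config, seed) are byte-identical
        "files": {
            "annotation": os.path.basename(ann_path),
            "cytosine_report": os.path.basename(cyt_path),
            "longreads": os.path.basename(lr_path),
            "shortreads": {c: os.path.basename(p) for c, p in sr_paths.items()},
            "truth": os.path.basename(truth_path),
        },
        "longread_count": int(sum(realized)),
        "shortread_library_sizes": sr_sizes,
        "config": _config_to_jsonable(config),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def planted_truth(outdir: str) -> pd.DataFrame:
    """Load the truth table of a bundle, checking it matches the annotation."""
    truth_path = os.path.join(outdir, "truth.tsv")
    ann_path = os.path.join(outdir, "annotation.gff3")
    if not os.path.exists(truth_path):
        raise FileNotFoundError(f"no truth table in {outdir}")
    truth = pd.read_csv(truth_path, sep="\t")
    ann = load_annotation(ann_path)
    if set(truth["gene_id"]) != set(ann.genes):
        raise ValueError("truth table and annotation disagree on gene ids")
    return truth
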