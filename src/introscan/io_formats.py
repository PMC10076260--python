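"""Standard-format I/O and the shared domain containers.

All genomic intervals are held internally in 0-based half-open
coordinates.  VCF positions are converted on read (POS - 1) and back on
write; exported BED files are therefore written verbatim.  Missing
alleles are encoded with the sentinel :data:`MISSING` (-1) and are
propagated, never imputed, by downstream statistics.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("introscan")

#: Sentinel for a missing allele in a haplotype matrix.
MISSING = -1

ANDEAN_GROUPS = ("AM_A1", "AM_A2", "AM_A3")
MESOAMERICAN_GROUPS = ("AM_M1", "AM_M2")
DONOR_GROUPS = MESOAMERICAN_GROUPS + ANDEAN_GROUPS

#: Genepool labels used for recipient accessions.
ANDEAN = "AND"
MESOAMERICAN = "MES"


def genepool_of(group: str) -> str:
    """Map a donor group label (e.g. ``AM_A1``) to its genepool."""
    if group in ANDEAN_GROUPS:
        return ANDEAN
    if group in MESOAMERICAN_GROUPS:
        return MESOAMERICAN
    raise ValueError(f"unknown donor group: {group!r}")


class VcfParseError(ValueError):
    """A malformed VCF record, reported with its line context."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotype matrix with coordinates and metadata.

    Attributes
    ----------
    chrom : array of str, per site
    pos : array of int, 0-based site positions, strictly increasing
        within each chromosome
    ref, alt : arrays of single-base allele strings
    haplotypes : int8 matrix of shape (2 * n_samples, n_sites) with
        entries in {0, 1, MISSING}; rows 2*i and 2*i+1 are the two
        haplotypes of sample i
    sample_ids : sample names, one per diploid accession
    phased : whether genotypes were phased on input
    qual : per-site QUAL score (optional)
    site_depth : per-site total read depth (optional)
    genotype_depth : (n_samples, n_sites) per-genotype depth (optional)
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    sample_ids: list
    phased: bool = True
    qual: np.ndarray | None = None
    site_depth: np.ndarray | None = None
    genotype_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def chrom_ids(self) -> list:
        """Chromosome names in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def sample_haplotype_rows(self, i: int) -> tuple[int, int]:
        return 2 * i, 2 * i + 1

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom

    def validate(self) -> None:
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype matrix must have 2 rows per sample")
        if self.haplotypes.shape[1] != len(self.pos):
            raise ValueError("haplotype matrix / position length mismatch")
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele codes must be 0, 1 or MISSING")
        for c in self.chrom_ids:
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(
                    f"positions not strictly increasing on {c}")

    # -- subsetting -----------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "HaplotypePanel":
        """Return a panel restricted to the given site indices (in order)."""
        index = np.asarray(index)
        return HaplotypePanel(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            haplotypes=self.haplotypes[:, index],
            sample_ids=list(self.sample_ids),
            phased=self.phased,
            qual=None if self.qual is None else self.qual[index],
            site_depth=(None if self.site_depth is None
                        else self.site_depth[index]),
            genotype_depth=(None if self.genotype_depth is None
                            else self.genotype_depth[:, index]),
        )

    def take_samples(self, names: Sequence[str]) -> "HaplotypePanel":
        idx = [self.sample_ids.index(n) for n in names]
        rows = np.ravel([(2 * i, 2 * i + 1) for i in idx])
        return HaplotypePanel(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            haplotypes=self.haplotypes[rows],
            sample_ids=list(names),
            phased=self.phased,
            qual=self.qual,
            site_depth=self.site_depth,
            genotype_depth=(None if self.genotype_depth is None
                            else self.genotype_depth[idx]),
        )

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            chrom=self.chrom.copy(), pos=self.pos.copy(),
            ref=self.ref.copy(), alt=self.alt.copy(),
            haplotypes=self.haplotypes.copy(),
            sample_ids=list(self.sample_ids), phased=self.phased,
            qual=None if self.qual is None else self.qual.copy(),
            site_depth=(None if self.site_depth is None
                        else self.site_depth.copy()),
            genotype_depth=(None if self.genotype_depth is None
                            else self.genotype_depth.copy()),
        )


@dataclass
class GroupAssignment:
    """Sample -> population label map with donor/recipient roles."""

    labels: dict
    roles: dict

    def __post_init__(self) -> None:
        for s, r in self.roles.items():
            if r not in ("donor", "recipient"):
                raise ValueError(f"role of {s!r} must be donor/recipient")

    def donors(self) -> list:
        return [s for s, r in self.roles.items() if r == "donor"]

    def recipients(self) -> list:
        return [s for s, r in self.roles.items() if r == "recipient"]

    def members(self, label: str) -> list:
        return [s for s, g in self.labels.items() if g == label]

    def group_of(self, sample: str) -> str:
        return self.labels[sample]

    def donor_groups(self) -> list:
        seen: dict = {}
        for s in self.donors():
            seen.setdefault(self.labels[s], None)
        return list(seen)


@dataclass
class AnnotationTable:
    """Per-variant effect classes and gene intervals.

    ``variants`` columns: chrom, pos (0-based), effect in
    {synonymous, missense, loss_of_function, other}, gene_id.
    ``genes`` columns: gene_id, chrom, start, end (0-based half-open).
    """

    variants: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end"]))

    EFFECTS = ("synonymous", "missense", "loss_of_function", "other")

    def __post_init__(self) -> None:
        bad = set(self.variants["effect"]) - set(self.EFFECTS)
        if bad:
            raise ValueError(f"unknown effect classes: {sorted(bad)}")

    def match_panel(self, panel: HaplotypePanel) -> np.ndarray:
        """Per-variant boolean: does the annotation hit a panel site?"""
        keys = set(zip(panel.chrom, panel.pos))
        return np.array([
            (c, p) in keys
            for c, p in zip(self.variants["chrom"], self.variants["pos"])
        ])

    def effect_of_sites(self, panel: HaplotypePanel) -> np.ndarray:
        """Effect class per panel site ('other' when unannotated)."""
        lut = {(c, p): e for c, p, e in zip(
            self.variants["chrom"], self.variants["pos"],
            self.variants["effect"])}
        return np.array([
            lut.get((c, p), "other")
            for c, p in zip(panel.chrom, panel.pos)
        ], dtype=object)


@dataclass
class RegionSet:
    """Genomic intervals (0-based half-open) with provenance metadata.

    ``df`` columns: chrom, start, end, plus optional support columns
    (e.g. ``n_snps``, ``mean_stat``).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.df.columns):
            raise ValueError("RegionSet requires chrom/start/end columns")
        if len(self.df):
            if (self.df["start"] < 0).any():
                raise ValueError("negative interval coordinate")
            if (self.df["start"] >= self.df["end"]).any():
                raise ValueError("interval with start >= end")
        self.df = self.df.sort_values(
            ["chrom", "start", "end"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> list:
        return list(zip(self.df["chrom"], self.df["start"], self.df["end"]))

    def total_span(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def merge(self, gap: int = 0) -> "RegionSet":
        """Merge intervals whose distance is <= gap (bedtools merge -d).

        Support columns ``n_snps`` are summed across merged members.
        """
        rows = []
        for chrom, sub in self.df.groupby("chrom", sort=True):
            sub = sub.sort_values(["start", "end"])
            cur = None
            for r in sub.itertuples(index=False):
                if cur is None:
                    cur = {"chrom": chrom, "start": r.start, "end": r.end,
                           "n_snps": getattr(r, "n_snps", 0)}
                elif r.start - cur["end"] <= gap:
                    cur["end"] = max(cur["end"], r.end)
                    cur["n_snps"] += getattr(r, "n_snps", 0)
                else:
                    rows.append(cur)
                    cur = {"chrom": chrom, "start": r.start, "end": r.end,
                           "n_snps": getattr(r, "n_snps", 0)}
            if cur is not None:
                rows.append(cur)
        cols = ["chrom", "start", "end"]
        if "n_snps" in self.df.columns:
            cols.append("n_snps")
        out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])
        return RegionSet(out[cols], provenance=self.provenance)

    def overlaps_any(self, other: "RegionSet") -> np.ndarray:
        """Per-interval boolean: overlaps at least one interval of other."""
        flags = np.zeros(len(self.df), dtype=bool)
        by_chrom: dict = {}
        for c, s, e in other.intervals():
            by_chrom.setdefault(c, []).append((s, e))
        for i, (c, s, e) in enumerate(self.intervals()):
            for (s2, e2) in by_chrom.get(c, ()):
                if s < e2 and s2 < e:
                    flags[i] = True
                    break
        return flags

    def intersect_filter(self, other: "RegionSet") -> "RegionSet":
        """Keep intervals overlapping at least one interval of other."""
        keep = self.overlaps_any(other)
        return RegionSet(self.df[keep].reset_index(drop=True),
                         provenance=self.provenance)

    def union(self, other: "RegionSet", gap: int = 0) -> "RegionSet":
        both = pd.concat([self.df[["chrom", "start", "end"]],
                          other.df[["chrom", "start", "end"]]],
                         ignore_index=True)
        return RegionSet(both, provenance=f"{self.provenance}|union").merge(gap)

    @staticmethod
    def empty(provenance: str = "") -> "RegionSet":
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]),
                         provenance=provenance)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, region_filter: RegionSet | None = None
             ) -> HaplotypePanel:
    """Read a VCF 4.x into a :class:`HaplotypePanel`.

    Only biallelic SNP records are kept; other records are skipped and
    counted.  Phase is taken from the genotype separator; the panel is
    flagged unphased if any kept genotype is unphased.  ``region_filter``
    restricts to sites overlapping the given intervals.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    keep_keys = None
    if region_filter is not None:
        keep_keys = {}
        for c, s, e in region_filter.intervals():
            keep_keys.setdefault(c, []).append((s, e))

    chroms, poss, refs, alts, quals, depths, gts, gdps = \
        [], [], [], [], [], [], [], []
    n_skipped = 0
    phased = True
    for v in vcf:
        if (len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1
                or v.ALT[0] not in "ACGT" or v.REF not in "ACGT"):
            n_skipped += 1
            continue
        pos0 = v.POS - 1
        if keep_keys is not None:
            hits = keep_keys.get(v.CHROM, ())
            if not any(s <= pos0 < e for s, e in hits):
                continue
        g = np.array(v.genotypes, dtype=object)  # rows [a1, a2, phased]
        col = np.full(2 * len(samples), MISSING, dtype=np.int8)
        for i, (a1, a2, ph) in enumerate(g):
            if a1 is not None and a1 >= 0:
                col[2 * i] = a1
            if a2 is not None and a2 >= 0:
                col[2 * i + 1] = a2
            if not ph and (a1, a2) != (-1, -1):
                phased = False
        chroms.append(v.CHROM)
        poss.append(pos0)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        info_dp = v.INFO.get("DP")
        depths.append(np.nan if info_dp is None else float(info_dp))
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        gdps.append(None if dp is None else dp[:, 0].astype(float))
        gts.append(col)

    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records",
                    n_skipped)
    if not gts:
        raise VcfParseError(f"no biallelic SNP records in {path}")

    have_gdp = all(g is not None for g in gdps)
    return HaplotypePanel(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        haplotypes=np.column_stack(gts),
        sample_ids=samples,
        phased=phased,
        qual=np.array(quals, dtype=float),
        site_depth=np.array(depths, dtype=float),
        genotype_depth=(np.column_stack(gdps) if have_gdp else None),
    )


def write_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write a panel as a minimal phased VCF 4.2."""
    sep = "|" if panel.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan\n")
        for c in panel.chrom_ids:
            last = int(panel.pos[panel.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={max(last, 1)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in panel.sample_ids) + "\n")
        H = panel.haplotypes
        for j in range(panel.n_sites):
            qual = "."
            if panel.qual is not None and np.isfinite(panel.qual[j]):
                q = panel.qual[j]
                qual = f"{q:g}"
            cells = []
            for i in range(panel.n_samples):
                a1, a2 = H[2 * i, j], H[2 * i + 1, j]
                s1 = "." if a1 == MISSING else str(int(a1))
                s2 = "." if a2 == MISSING else str(int(a2))
                cells.append(f"{s1}{sep}{s2}")
            fh.write(f"{panel.chrom[j]}\t{panel.pos[j] + 1}\t.\t"
                     f"{panel.ref[j]}\t{panel.alt[j]}\t{qual}\t.\t.\tGT\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# BED and tables
# ---------------------------------------------------------------------------

def write_bed(regions: RegionSet, path: str) -> None:
    """Write a RegionSet as BED3+ (0-based half-open), sorted."""
    with open(path, "w") as fh:
        fh.write(f"# introscan regions: {regions.provenance}\n")
        extra = [c for c in regions.df.columns
                 if c not in ("chrom", "start", "end")]
        for r in regions.df.itertuples(index=False):
            line = f"{r.chrom}\t{int(r.start)}\t{int(r.end)}"
            for c in extra:
                line += f"\t{getattr(r, c)}"
            fh.write(line + "\n")


def read_bed(path: str, provenance: str = "") -> RegionSet:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append({"chrom": parts[0], "start": int(parts[1]),
                         "end": int(parts[2])})
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                     provenance=provenance)


def read_groups(path: str) -> GroupAssignment:
    """Read a TSV with columns sample, group, role."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return GroupAssignment(
        labels=dict(zip(df["sample"], df["group"])),
        roles=dict(zip(df["sample"], df["role"])),
    )


def write_groups(groups: GroupAssignment, path: str) -> None:
    df = pd.DataFrame({
        "sample": list(groups.labels),
        "group": [groups.labels[s] for s in groups.labels],
        "role": [groups.roles[s] for s in groups.labels],
    })
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str, genes_path: str | None = None
                    ) -> AnnotationTable:
    """Read variant effects (TSV: chrom, pos0, effect, gene_id) and,
    optionally, gene intervals (TSV: gene_id, chrom, start, end)."""
    var = pd.read_csv(path, sep="\t")
    genes = (pd.read_csv(genes_path, sep="\t") if genes_path else
             pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]))
    return AnnotationTable(variants=var, genes=genes)


def read_traits(path: str) -> pd.DataFrame:
    """Read a trait table (TSV: accession, trait, environment,
    replicate, value)."""
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the published operating values."""

    window_bp: int = 10_000          # painting / FST window
    prob_threshold: float = 0.8      # window assignment probability
    gap_bp: int = 50_000             # block gap joining
    min_block_windows: int = 2       # drop single-window blocks
    slop_bp: int = 2_500             # excess-region slop
    merge_bp: int = 10_000           # excess-region merge distance
    min_region_snps: int = 3         # excess-region support
    selection_region_halfwidth: int = 5_000   # 10-kb region per SNP
    selection_merge_bp: int = 5_000  # merge distance for selection regions
    p_threshold: float = 1e-3
    fdr: float = 0.05
    fst_top_quantile: float = 0.05   # FST-outlier window filter
    rho_per_bp: float = 1e-8         # recombination rate for painting
    n_em_iter: int = 10              # ChromoPainter-style EM iterations
    n_hapflk_fits: int = 20          # independent EM fits averaged
    n_clusters: int = 5              # initial haplotype-cluster K
    thin_bp: int = 250_000           # kinship thinning
    theta_window_bp: int = 100_000   # diversity window
    ld_maf: float = 0.1
    ld_max_dist: int = 5_000_000
    interchrom_thin_bp: int = 10_000
    interchrom_maf: float = 0.05
    interchrom_r2_min: float = 0.8
    interchrom_merge_bp: int = 100_000
    interchrom_min_width: int = 500_000
    h2_min: float = 0.65             # metabolite heritability filter
    qst_outlier_quantile: float = 97.5

    def validate(self) -> None:
        if not 0 < self.prob_threshold <= 1:
            raise ValueError("prob_threshold must lie in (0, 1]")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        for name in ("window_bp", "gap_bp", "slop_bp", "merge_bp",
                     "thin_bp", "theta_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.interchrom_r2_min <= 1:
            raise ValueError("interchrom_r2_min must lie in [0, 1]")


def load_config(path: str | None = None,
                overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected.

    An empty or missing file yields the full default configuration.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    for f in fields(cfg):
        logger.info("config %s = %r", f.name, getattr(cfg, f.name))
    return cfg


def setup_logging(logfile: str | None = None,
                  level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s "
                               "%(message)s")
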