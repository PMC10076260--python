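"""Synthetic admixed crop panels with known ancestry tracts.

The generator emulates the structure of a two-genepool crop complex:
two deeply diverged genepools (Mesoamerican-like and Andean-like), each
subdivided into races (M1, M2 and A1, A2, A3), differentiated under a
nested Balding-Nichols model with tunable drift; recipient (European-
like) accessions whose haplotypes are mosaics of donor ancestry laid
down by a Markov switch process; near-complete selfing producing
homozygous inbred lines; per-variant effect classes; and group-
structured quantitative traits with replicates.

Ancestry along a recipient haplotype follows a continuous switch
process: switch events occur at rate ``g * r`` per bp (``g`` admixture
age in generations, ``r`` recombination rate per bp per generation) and
each event draws the minor genepool with probability ``m``.  Minor-
ancestry tract lengths are therefore exponential with rate
``g * r * (1 - m)``; tracts are truncated at chromosome ends.  Alleles
are copied from a random donor haplotype of the tract's race with a
small miscopy rate, so downstream painting is non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


import numpy as np
import pandas as pd

from .io_formats import (ANDEAN, ANDEAN_GROUPS, DONOR_GROUPS,
                         MESOAMERICAN, MESOAMERICAN_GROUPS, AnnotationTable,
                         GroupAssignment, HaplotypePanel, genepool_of)


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults describe a desk-scale version of a resequenced two-
    genepool crop panel: strong inter-genepool differentiation
    (F = 0.4), weaker race structure (F = 0.1), recent admixture
    (g = 20 generations) contributing a minor-ancestry fraction
    m = 0.1, uniform recombination at 1e-8 per bp, and fully selfed
    (homozygous) lines.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len_bp: int = 5_000_000
    n_sites: int = 3000                      # total across chromosomes
    f_divergence: float = 0.4                # genepool-level drift
    f_subgroup: float = 0.1                  # race-level drift
    donor_group_sizes: dict = field(default_factory=lambda: {
        "AM_M1": 12, "AM_M2": 12, "AM_A1": 12, "AM_A2": 12, "AM_A3": 12})
    n_recipients: int = 40
    recipient_andean_fraction: float = 0.6   # share of EU_AND-like majors
    m: float = 0.1                           # minor-ancestry proportion
    g: int = 20                              # admixture age, generations
    recomb_rate: float = 1e-8                # per bp per generation
    selfing: bool = True
    miscopy_rate: float = 1e-3
    effect_proportions: dict = field(default_factory=lambda: {
        "synonymous": 0.25, "missense": 0.20,
        "loss_of_function": 0.02, "other": 0.53})
    # trait model
    sigma2_between: float = 2.0              # between ancestry groups
    sigma2_within: float = 1.0               # between lines within group
    sigma2_env: float = 0.0                  # environment main effect
    sigma2_rep: float = 1.0                  # replicate noise
    n_reps: int = 3
    n_envs: int = 1
    # optional engineered adaptive-introgression loci:
    # (chrom, start, end, carrier_frequency, genepool) forcing the
    # given ancestry in carriers regardless of their major genepool
    sweep_regions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.m <= 1:
            raise ValueError("admixture proportion m must lie in [0, 1]")
        if self.g < 1:
            raise ValueError("admixture age g must be >= 1")
        for v in (self.sigma2_between, self.sigma2_within,
                  self.sigma2_env, self.sigma2_rep):
            if v < 0:
                raise ValueError("variance components must be >= 0")
        if any(n < 2 for n in self.donor_group_sizes.values()):
            raise ValueError("donor group sizes must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def chrom_names(self) -> list:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chrom)]


@dataclass
class TruthTracts:
    """Ground-truth ancestry tracts per recipient haplotype.

    ``tracts[(sample_id, h)]`` with h in {0, 1} is a per-chromosome dict
    of lists of (start, end, race) tuples tiling [0, chrom_len).
    """

    tracts: dict
    chrom_len: int
    major_genepool: dict  # sample_id -> AND / MES

    def haplotype_keys(self) -> list:
        return list(self.tracts)

    def segments(self, key, chrom: str):
        return self.tracts[key][chrom]

    def ancestry_at(self, key, chrom: str, positions: np.ndarray
                    ) -> np.ndarray:
        """Race label for each position on a haplotype (vectorised)."""
        segs = self.tracts[key][chrom]
        starts = np.array([s for s, _, _ in segs])
        labels = np.array([g for _, _, g in segs], dtype=object)
        idx = np.searchsorted(starts, positions, side="right") - 1
        return labels[idx]

    def genepool_at(self, key, chrom: str, positions: np.ndarray
                    ) -> np.ndarray:
        races = self.ancestry_at(key, chrom, positions)
        return np.array([genepool_of(r) for r in races], dtype=object)

    def minor_fraction(self, key) -> float:
        """Fraction of the haplotype genome in its minor genepool."""
        sid = key[0]
        major = self.major_genepool[sid]
        tot = minor = 0
        for chrom, segs in self.tracts[key].items():
            for s, e, race in segs:
                tot += e - s
                if genepool_of(race) != major:
                    minor += e - s
        return minor / tot

    def minor_tract_lengths(self, key, min_length: int = 0) -> list:
        """Lengths of maximal minor-genepool runs on a haplotype.

        Adjacent segments of different races but the same genepool are
        merged before measuring, mirroring genepool-level block calls.
        """
        sid = key[0]
        major = self.major_genepool[sid]
        out = []
        for chrom, segs in self.tracts[key].items():
            run = 0
            for s, e, race in segs:
                if genepool_of(race) != major:
                    run += e - s
                else:
                    if run >= min_length and run > 0:
                        out.append(run)
                    run = 0
            if run >= min_length and run > 0:
                out.append(run)
        return out


# ---------------------------------------------------------------------------
# Allele frequencies (nested Balding-Nichols)
# ---------------------------------------------------------------------------

def _balding_nichols(p: np.ndarray, f: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw drifted frequencies around p with differentiation f."""
    p = np.clip(p, 1e-6, 1 - 1e-6)   # guard fixed parent frequencies
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b)


def simulate_frequencies(config: SimConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, dict]:
    """Ancestral and per-race allele frequencies.

    The ancestral frequency is Uniform(0.05, 0.95) per site; each
    genepool drifts from it with ``f_divergence`` and each race drifts
    from its genepool with ``f_subgroup`` (nested Balding-Nichols).

    Returns (ancestral p, {race label: frequencies}).
    """
    if not 0 < config.f_divergence < 1:
        raise ValueError("f_divergence must lie in (0, 1)")
    if not 0 < config.f_subgroup < 1:
        raise ValueError("f_subgroup must lie in (0, 1)")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.n_sites
    p_anc = rng.uniform(0.05, 0.95, size=L)
    pool_freq = {
        MESOAMERICAN: _balding_nichols(p_anc, config.f_divergence, rng),
        ANDEAN: _balding_nichols(p_anc, config.f_divergence, rng),
    }
    group_freq = {}
    for grp in config.donor_group_sizes:
        base = pool_freq[genepool_of(grp)]
        group_freq[grp] = _balding_nichols(base, config.f_subgroup, rng)
    return p_anc, group_freq


# ---------------------------------------------------------------------------
# Donor panel
# ---------------------------------------------------------------------------

def _site_coordinates(config: SimConfig, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Spread n_sites across chromosomes at sorted unique positions."""
    per = np.full(config.n_chrom, config.n_sites // config.n_chrom)
    per[: config.n_sites % config.n_chrom] += 1
    chroms, poss = [], []
    for c, n in zip(config.chrom_names, per):
        pos = np.sort(rng.choice(config.chrom_len_bp, size=n,
                                 replace=False))
        chroms.extend([c] * n)
        poss.append(pos)
    return np.array(chroms, dtype=object), np.concatenate(poss)


def simulate_donors(config: SimConfig,
                    group_freq: dict,
                    rng: np.random.Generator,
                    chrom: np.ndarray, pos: np.ndarray
                    ) -> tuple[HaplotypePanel, GroupAssignment]:
    """Draw donor haplotypes from race frequencies (selfed lines)."""
    hap_rows, sample_ids, labels, roles = [], [], {}, {}
    for grp, n in config.donor_group_sizes.items():
        freqs = group_freq[grp]
        for i in range(n):
            sid = f"{grp}_d{i:03d}"
            h1 = (rng.random(config.n_sites) < freqs).astype(np.int8)
            if config.selfing:
                h2 = h1.copy()
            else:
                h2 = (rng.random(config.n_sites) < freqs).astype(np.int8)
            hap_rows.extend([h1, h2])
            sample_ids.append(sid)
            labels[sid] = grp
            roles[sid] = "donor"
    panel = HaplotypePanel(
        chrom=chrom, pos=pos,
        ref=np.full(config.n_sites, "A", dtype=object),
        alt=np.full(config.n_sites, "T", dtype=object),
        haplotypes=np.vstack(hap_rows),
        sample_ids=sample_ids,
    )
    return panel, GroupAssignment(labels=labels, roles=roles)


# ---------------------------------------------------------------------------
# Recipient mosaics
# ---------------------------------------------------------------------------

def _draw_ancestry_segments(chrom_len: int, major: str, m: float,
                            switch_rate: float,
                            rng: np.random.Generator) -> list:
    """Piecewise-constant genepool ancestry on [0, chrom_len).

    Switch events form a Poisson process with the given per-bp rate;
    each event (and the chromosome start) draws the minor genepool with
    probability m.  Returns (start, end, genepool) segments; adjacent
    same-state segments are merged.
    """
    minor = ANDEAN if major == MESOAMERICAN else MESOAMERICAN
    breaks = [0]
    x = 0.0
    if switch_rate > 0:
        while True:
            x += rng.exponential(1.0 / switch_rate)
            if x >= chrom_len:
                break
            breaks.append(int(x))
    breaks.append(chrom_len)
    segs = []
    for i in range(len(breaks) - 1):
        state = minor if rng.random() < m else major
        if breaks[i] == breaks[i + 1]:
            continue
        if segs and segs[-1][2] == state:
            segs[-1] = (segs[-1][0], breaks[i + 1], state)
        else:
            segs.append((breaks[i], breaks[i + 1], state))
    return segs


def _override_segments(segs: list, start: int, end: int,
                       state: str) -> list:
    """Force [start, end) to the given genepool state."""
    out = []
    for s, e, g in segs:
        if e <= start or s >= end:
            out.append((s, e, g))
            continue
        if s < start:
            out.append((s, start, g))
        if e > end:
            out.append((end, e, g))
    out.append((start, end, state))
    out.sort()
    merged: list = []
    for s, e, g in out:
        if merged and merged[-1][2] == g and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e, g)
        else:
            merged.append((s, e, g))
    return merged


def _assign_races(segs: list, by_pool: dict,
                  rng: np.random.Generator) -> list:
    """Refine genepool segments to race-level tracts."""
    out = []
    for s, e, pool in segs:
        race = by_pool[pool][rng.integers(len(by_pool[pool]))]
        out.append((s, e, race))
    return out


def simulate_recipients(config: SimConfig,
                        donor_panel: HaplotypePanel,
                        donor_groups: GroupAssignment,
                        rng: np.random.Generator
                        ) -> tuple[HaplotypePanel, TruthTracts]:
    """Admixed recipient lines copied from donor haplotypes.

    Each recipient has a major genepool; ancestry along each haplotype
    follows the Markov switch process; alleles are copied from a
    uniformly chosen donor haplotype of the tract's race, flipped with
    the miscopy rate.  With selfing, the two haplotypes of a line are
    identical (tracts and alleles).
    """
    by_pool = {MESOAMERICAN: [], ANDEAN: []}
    for grp in donor_groups.donor_groups():
        by_pool[genepool_of(grp)].append(grp)
    for pool, races in by_pool.items():
        if not races:
            raise ValueError(f"no donor races available for {pool}")
    donor_hap_rows = {}  # race -> row indices into donor haplotypes
    for grp in donor_groups.donor_groups():
        rows = []
        for s in donor_groups.members(grp):
            i = donor_panel.sample_ids.index(s)
            rows.extend([2 * i, 2 * i + 1])
        donor_hap_rows[grp] = np.array(rows)

    switch_rate = config.g * config.recomb_rate
    n_and = int(round(config.n_recipients
                      * config.recipient_andean_fraction))
    majors = [ANDEAN] * n_and + [MESOAMERICAN] * (config.n_recipients - n_and)

    site_pos_by_chrom = {
        c: (np.flatnonzero(donor_panel.chrom == c),
            donor_panel.pos[donor_panel.chrom == c])
        for c in config.chrom_names}

    hap_rows, sample_ids = [], []
    tracts: dict = {}
    major_of: dict = {}
    for k, major in enumerate(majors):
        sid = f"EU_r{k:03d}"
        sample_ids.append(sid)
        major_of[sid] = major
        n_hap = 1 if config.selfing else 2
        built = []
        for h in range(n_hap):
            hap = np.zeros(config.n_sites, dtype=np.int8)
            per_chrom: dict = {}
            for chrom in config.chrom_names:
                segs = _draw_ancestry_segments(
                    config.chrom_len_bp, major, config.m, switch_rate, rng)
                for (c2, s2, e2, freq, pool) in config.sweep_regions:
                    if c2 == chrom and rng.random() < freq:
                        segs = _override_segments(segs, s2, e2, pool)
                segs = _assign_races(segs, by_pool, rng)
                per_chrom[chrom] = segs
                idx, pos = site_pos_by_chrom[chrom]
                for s, e, race in segs:
                    lo = np.searchsorted(pos, s, side="left")
                    hi = np.searchsorted(pos, e, side="left")
                    if hi == lo:
                        continue
                    rows = donor_hap_rows[race]
                    src = rows[rng.integers(len(rows))]
                    sites = idx[lo:hi]
                    hap[sites] = donor_panel.haplotypes[src, sites]
            flip = rng.random(config.n_sites) < config.miscopy_rate
            hap[flip] = 1 - hap[flip]
            built.append((hap, per_chrom))
        if config.selfing:
            built.append(built[0])
        for h in range(2):
            hap, per_chrom = built[h]
            hap_rows.append(hap.copy())
            tracts[(sid, h)] = per_chrom

    panel = HaplotypePanel(
        chrom=donor_panel.chrom, pos=donor_panel.pos,
        ref=donor_panel.ref, alt=donor_panel.alt,
        haplotypes=np.vstack(hap_rows), sample_ids=sample_ids,
    )
    truth = TruthTracts(tracts=tracts, chrom_len=config.chrom_len_bp,
                        major_genepool=major_of)
    return panel, truth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig, panel: HaplotypePanel,
                        rng: np.random.Generator,
                        gene_len: int = 4000,
                        gene_spacing: int = 20_000) -> AnnotationTable:
    """Random effect classes per site and a regular gene grid."""
    classes = list(config.effect_proportions)
    probs = np.array([config.effect_proportions[c] for c in classes])
    probs = probs / probs.sum()
    effects = rng.choice(classes, size=panel.n_sites, p=probs)

    gene_rows = []
    for chrom in panel.chrom_ids:
        gid = 0
        for start in range(0, config.chrom_len_bp, gene_spacing):
            gene_rows.append({"gene_id": f"{chrom}_g{gid:04d}",
                              "chrom": chrom, "start": start,
                              "end": min(start + gene_len,
                                         config.chrom_len_bp)})
            gid += 1
    genes = pd.DataFrame(gene_rows)

    gene_of = np.full(panel.n_sites, "", dtype=object)
    for chrom, sub in genes.groupby("chrom"):
        mask = panel.chrom == chrom
        pos = panel.pos[mask]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["gene_id"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        out = np.where(ok, ids[np.clip(j, 0, None)], "")
        gene_of[np.flatnonzero(mask)] = out

    variants = pd.DataFrame({
        "chrom": panel.chrom, "pos": panel.pos,
        "effect": effects, "gene_id": gene_of,
    })
    return AnnotationTable(variants=variants, genes=genes)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(config: SimConfig, group_of: dict,
                    rng: np.random.Generator | None = None,
                    trait: str = "trait") -> pd.DataFrame:
    """Group-structured trait with replicate noise.

    value = group mean (var sigma2_between) + line deviation
    (sigma2_within) + environment effect (sigma2_env) + replicate noise
    (sigma2_rep).  Expected broad-sense H2 (single environment) is
    (sigma2_between + sigma2_within) / (total).
    """
    if config.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    accs = list(group_of)
    groups = sorted(set(group_of.values()))
    n_acc, E, R = len(accs), config.n_envs, config.n_reps
    gmean = dict(zip(groups, rng.normal(
        0, np.sqrt(config.sigma2_between), size=len(groups))))
    line = (np.array([gmean[group_of[a]] for a in accs])
            + rng.normal(0, np.sqrt(config.sigma2_within), size=n_acc))
    envs = [f"env{j + 1}" for j in range(E)]
    emean = (rng.normal(0, np.sqrt(config.sigma2_env), size=E)
             if config.sigma2_env > 0 else np.zeros(E))
    noise = rng.normal(0, np.sqrt(config.sigma2_rep),
                       size=(n_acc, E, R))
    values = line[:, None, None] + emean[None, :, None] + noise
    return pd.DataFrame({
        "accession": np.repeat(accs, E * R),
        "trait": trait,
        "environment": np.tile(np.repeat(envs, R), n_acc),
        "replicate": np.tile(np.arange(1, R + 1), n_acc * E),
        "value": values.ravel(),
    })


def simulate_trait_matrix(config: SimConfig, group_of: dict,
                          n_traits: int,
                          rng: np.random.Generator | None = None,
                          prefix: str = "met") -> pd.DataFrame:
    """Stack of independent group-structured traits (metabolite-like)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return pd.concat(
        [simulate_traits(config, group_of, rng, trait=f"{prefix}{i:04d}")
         for i in range(n_traits)], ignore_index=True)


# ---------------------------------------------------------------------------
# One-call panel
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanel:
    """Complete synthetic study: donors + recipients + metadata."""

    config: SimConfig
    donors: HaplotypePanel
    recipients: HaplotypePanel
    combined: HaplotypePanel
    groups: GroupAssignment
    truth: TruthTracts
    annotation: AnnotationTable
    group_freq: dict


def simulate_panel(config: SimConfig) -> SyntheticPanel:
    """Generate the full synthetic study from (config, seed)."""
    rng = np.random.default_rng(config.seed)
    chrom, pos = _site_coordinates(config, rng)
    cfg = replace(config)
    _, group_freq = simulate_frequencies(cfg, rng)
    donors, donor_groups = simulate_donors(cfg, group_freq, rng, chrom, pos)
    recips, truth = simulate_recipients(cfg, donors, donor_groups, rng)
    annotation = simulate_annotation(cfg, donors, rng)

    labels = dict(donor_groups.labels)
    roles = dict(donor_groups.roles)
    for sid in recips.sample_ids:
        labels[sid] = "EU"
        roles[sid] = "recipient"
    combined = HaplotypePanel(
        chrom=chrom, pos=pos, ref=donors.ref, alt=donors.alt,
        haplotypes=np.vstack([donors.haplotypes, recips.haplotypes]),
        sample_ids=list(donors.sample_ids) + list(recips.sample_ids),
    )
    groups = GroupAssignment(labels=labels, roles=roles)
    return SyntheticPanel(config=config, donors=donors, recipients=recips,
                          combined=combined, groups=groups, truth=truth,
                          annotation=annotation, group_freq=group_freq)
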