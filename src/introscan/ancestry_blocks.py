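"""Window-level ancestry assignment, genepool calls, introgression
blocks and ancestry masks.

Per-SNP group probabilities are averaged in 10-kb non-overlapping
windows; a window is assigned to a donor group when its mean
probability reaches 0.8, otherwise it is "unknown".  An accession's
genepool is called from (a) the total proportion of assigned windows
per genepool and (b) the per-chromosome majority vote, requiring
agreement.  Introgression blocks are runs of other-genepool windows on
a haplotype, joined across gaps of at most 50 kb and filtered to drop
single-window (10 kb) blocks; the per-accession distribution of block
lengths is summarised by its median.  Masking sets a haplotype's
alleles to missing wherever its window is attributed to the other
genepool or is unknown, yielding one masked panel per ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (ANDEAN, ANDEAN_GROUPS, MESOAMERICAN,
                         MESOAMERICAN_GROUPS, MISSING, HaplotypePanel,
                         RegionSet, genepool_of)
from .painting import PaintingResult

logger = logging.getLogger("introscan")

UNKNOWN = "unknown"


@dataclass
class AncestryWindowMap:
    """Per-haplotype window ancestry labels.

    ``windows`` columns: chrom, start, end (tiling each chromosome).
    ``labels`` is (n_haplotypes, n_windows) of donor-group labels or
    "unknown"; ``mean_probs`` is (n_haplotypes, n_windows, n_groups).
    """

    windows: pd.DataFrame
    labels: np.ndarray
    mean_probs: np.ndarray
    group_names: list
    hap_ids: list
    window_bp: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def hap_index(self, sample_id: str, h: int) -> int:
        return self.hap_ids.index((sample_id, h))

    def sample_ids(self) -> list:
        seen: dict = {}
        for sid, _ in self.hap_ids:
            seen.setdefault(sid, None)
        return list(seen)

    def genepool_labels(self) -> np.ndarray:
        """Labels collapsed to genepool level (AND / MES / unknown)."""
        out = np.full(self.labels.shape, UNKNOWN, dtype=object)
        for g in ANDEAN_GROUPS:
            out[self.labels == g] = ANDEAN
        for g in MESOAMERICAN_GROUPS:
            out[self.labels == g] = MESOAMERICAN
        return out


@dataclass
class IntrogressionBlock:
    """A run of other-genepool windows on one haplotype."""

    sample_id: str
    hap: int
    chrom: str
    start: int
    end: int
    ancestry: str          # genepool of the introgressed material
    n_windows: int         # supporting other-genepool windows

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenepoolCall:
    """Genepool assignment of one recipient accession."""

    accession_id: str
    call: str | None                  # AND / MES / None when ambiguous
    andean_proportion: float          # share of assigned windows
    mesoamerican_proportion: float
    unknown_proportion: float
    chromosome_votes: dict            # chrom -> AND / MES / tie
    ambiguous: bool = False


def assign_windows(painting: PaintingResult, window_bp: int = 10_000,
                   prob: float = 0.8,
                   chrom_len: dict | None = None) -> AncestryWindowMap:
    """Average per-SNP probabilities in tiling windows and label them.

    Windows tile each chromosome from 0 to its length (final partial
    window kept); a window with no SNPs is "unknown".
    """
    chroms: list = []
    starts: list = []
    for c in dict.fromkeys(painting.chrom):
        if chrom_len and c in chrom_len:
            length = chrom_len[c]
        else:
            length = int(painting.pos[painting.chrom == c].max()) + 1
        edges = np.arange(0, length, window_bp)
        chroms.extend([c] * len(edges))
        starts.extend(edges.tolist())
    windows = pd.DataFrame({"chrom": chroms, "start": starts})
    ends = []
    for c, s in zip(windows["chrom"], windows["start"]):
        if chrom_len and c in chrom_len:
            ends.append(min(s + window_bp, chrom_len[c]))
        else:
            ends.append(s + window_bp)
    windows["end"] = ends

    n_hap = painting.probs.shape[0]
    n_groups = len(painting.group_names)
    W = len(windows)
    mean_probs = np.zeros((n_hap, W, n_groups))
    labels = np.full((n_hap, W), UNKNOWN, dtype=object)
    for w, (c, s, e) in enumerate(zip(windows["chrom"], windows["start"],
                                      windows["end"])):
        mask = (painting.chrom == c) & (painting.pos >= s) \
            & (painting.pos < e)
        if not mask.any():
            continue
        mp = painting.probs[:, mask].mean(axis=1)
        mean_probs[:, w] = mp
        best = mp.argmax(axis=1)
        ok = mp[np.arange(n_hap), best] >= prob
        for i in np.flatnonzero(ok):
            labels[i, w] = painting.group_names[best[i]]
    return AncestryWindowMap(windows=windows, labels=labels,
                             mean_probs=mean_probs,
                             group_names=painting.group_names,
                             hap_ids=painting.hap_ids, window_bp=window_bp)


def call_genepool(wmap: AncestryWindowMap, sample_id: str) -> GenepoolCall:
    """Apply the two assignment criteria to one accession."""
    rows = [wmap.hap_index(sample_id, 0), wmap.hap_index(sample_id, 1)]
    gl = wmap.genepool_labels()[rows]           # (2, W)
    n_and = int((gl == ANDEAN).sum())
    n_mes = int((gl == MESOAMERICAN).sum())
    n_unk = int((gl == UNKNOWN).sum())
    if n_and + n_mes == 0:
        raise ValueError(f"accession {sample_id} unassignable: "
                         "all windows unknown")
    p_and = n_and / (n_and + n_mes)
    p_mes = n_mes / (n_and + n_mes)
    votes: dict = {}
    for c in dict.fromkeys(wmap.windows["chrom"]):
        in_c = (wmap.windows["chrom"] == c).to_numpy()
        a = int((gl[:, in_c] == ANDEAN).sum())
        m = int((gl[:, in_c] == MESOAMERICAN).sum())
        votes[c] = ANDEAN if a > m else MESOAMERICAN if m > a else "tie"
    vote_and = sum(v == ANDEAN for v in votes.values())
    vote_mes = sum(v == MESOAMERICAN for v in votes.values())
    crit_a = ANDEAN if p_and > 0.5 else MESOAMERICAN if p_mes > 0.5 else None
    crit_b = (ANDEAN if vote_and > vote_mes
              else MESOAMERICAN if vote_mes > vote_and else None)
    ambiguous = crit_a is None or crit_b is None or crit_a != crit_b
    call = None if ambiguous else crit_a
    if ambiguous:
        logger.info("accession %s: ambiguous genepool call "
                    "(criteria %s vs %s)", sample_id, crit_a, crit_b)
    return GenepoolCall(accession_id=sample_id, call=call,
                        andean_proportion=p_and,
                        mesoamerican_proportion=p_mes,
                        unknown_proportion=n_unk / gl.size,
                        chromosome_votes=votes, ambiguous=ambiguous)


def call_all_genepools(wmap: AncestryWindowMap) -> dict:
    return {sid: call_genepool(wmap, sid) for sid in wmap.sample_ids()}


def extract_blocks(wmap: AncestryWindowMap, genepool_calls: dict,
                   gap_bp: int = 50_000, min_windows: int = 2
                   ) -> tuple[list, dict]:
    """Introgression blocks per haplotype and per-accession medians.

    For an accession called genepool G, other-genepool windows are
    merged when consecutive; runs separated by at most ``gap_bp`` are
    joined (bridged unknown/same-genepool windows do not add support);
    blocks supported by fewer than ``min_windows`` windows are dropped.
    Returns (blocks, {accession: median length or nan}).
    """
    gl = wmap.genepool_labels()
    win = wmap.windows
    blocks: list = []
    medians: dict = {}
    for sid, call in genepool_calls.items():
        if call.call is None:
            logger.info("accession %s excluded from blocks (ambiguous)",
                        sid)
            medians[sid] = float("nan")
            continue
        other = MESOAMERICAN if call.call == ANDEAN else ANDEAN
        lengths: list = []
        for h in (0, 1):
            row = gl[wmap.hap_index(sid, h)]
            for chrom in dict.fromkeys(win["chrom"]):
                in_c = np.flatnonzero((win["chrom"] == chrom).to_numpy())
                hits = in_c[row[in_c] == other]
                if len(hits) == 0:
                    continue
                # consecutive-window runs -> candidate intervals
                runs: list = []
                start_w = prev = hits[0]
                count = 1
                for w in hits[1:]:
                    if w == prev + 1:
                        prev = w
                        count += 1
                    else:
                        runs.append((start_w, prev, count))
                        start_w = prev = w
                        count = 1
                runs.append((start_w, prev, count))
                # join runs whose genomic gap is <= gap_bp
                joined: list = []
                for (w0, w1, n) in runs:
                    s = int(win["start"].iloc[w0])
                    e = int(win["end"].iloc[w1])
                    if joined and s - joined[-1][1] <= gap_bp:
                        joined[-1] = (joined[-1][0], e, joined[-1][2] + n)
                    else:
                        joined.append((s, e, n))
                for (s, e, n) in joined:
                    if n < min_windows:
                        continue
                    blocks.append(IntrogressionBlock(
                        sample_id=sid, hap=h, chrom=chrom, start=s,
                        end=e, ancestry=other, n_windows=n))
                    lengths.append(e - s)
        medians[sid] = float(np.median(lengths)) if lengths else float("nan")
    return blocks, medians


def blocks_to_regions(blocks: list) -> RegionSet:
    df = pd.DataFrame([{
        "chrom": b.chrom, "start": b.start, "end": b.end,
        "sample": b.sample_id, "hap": b.hap, "ancestry": b.ancestry,
        "n_snps": b.n_windows,
    } for b in blocks], columns=["chrom", "start", "end", "sample",
                                 "hap", "ancestry", "n_snps"])
    return RegionSet(df, provenance="introgression-blocks")


def mask_introgression(panel: HaplotypePanel, wmap: AncestryWindowMap
                       ) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Build the (Andean-masked, Mesoamerican-masked) panel pair.

    In the Andean-masked panel, alleles are set to missing on each
    haplotype wherever its window label is Mesoamerican or unknown
    (and vice versa), so each masked panel contains single-ancestry
    material only.  Idempotent.
    """
    gl = wmap.genepool_labels()
    win = wmap.windows
    # window index per panel site
    site_window = np.full(panel.n_sites, -1, dtype=int)
    for chrom in dict.fromkeys(win["chrom"]):
        wc = (win["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(wc)
        starts = win["start"].to_numpy()[wc]
        in_c = panel.chrom == chrom
        j = np.searchsorted(starts, panel.pos[in_c], side="right") - 1
        valid = j >= 0
        tgt = np.full(int(in_c.sum()), -1, dtype=int)
        tgt[valid] = idx[j[valid]]
        site_window[np.flatnonzero(in_c)] = tgt

    hap_rows = {hid: r for r, hid in enumerate(wmap.hap_ids)}
    out = []
    for keep_pool in (ANDEAN, MESOAMERICAN):
        H = panel.haplotypes.copy()
        for i, sid in enumerate(panel.sample_ids):
            for h in (0, 1):
                r = hap_rows.get((sid, h))
                if r is None:
                    continue
                lab = gl[r][site_window]
                kill = (lab != keep_pool) | (site_window < 0)
                H[2 * i + h, kill] = MISSING
        out.append(HaplotypePanel(
            chrom=panel.chrom, pos=panel.pos, ref=panel.ref,
            alt=panel.alt, haplotypes=H, sample_ids=panel.sample_ids,
            phased=panel.phased, qual=panel.qual,
            site_depth=panel.site_depth,
            genotype_depth=panel.genotype_depth))
    return out[0], out[1]
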