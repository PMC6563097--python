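"""DMR calling, gene association, and Fisher gene-set enrichment.

A differentially methylated region (DMR) is called by a two-criterion
windowed rule over per-CG p-values:

1. a 2 kb window centered on a DMC containing >= 2 CGs with p <= 0.001
   (the DMC itself included), or
2. >= 3 CGs with p < 0.001 whose positional span is <= 2 kb (maximal runs
   found by a sorted sweep).

Qualifying regions on the same chromosome whose contributing-CG sets
overlap are merged; the reported span is the min..max of contributing CG
positions.  Note the deliberate asymmetry: criterion 1 uses p <= 0.001 and
criterion 2 uses p < 0.001.

Features (DMCs or DMRs) are associated with every gene whose interval
extended by 10 kb they intersect, with a strand-aware signed distance
(0 inside the gene body, negative upstream of the TSS, positive downstream
of the TES).  Enrichment is a one-sided Fisher exact test per gene set with
a minimum-hits cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


@dataclass
class DMRRecord:
    chrom: str
    start: int
    stop: int
    n_cg: int
    mean_meth_diff: float
    criterion: str                 # '1', '2' or 'both'
    sites: list = field(default_factory=list)  # contributing (chrom, pos)

    @property
    def dmr_id(self) -> str:
        return f"{self.chrom}.{self.start}.{self.stop}"


def call_dmrs(
    sites: pd.DataFrame,
    window_bp: int = 2000,
    p_thresh: float = 0.001,
) -> list:
    """Call DMRs from a per-site table with columns chrom, pos, p_value,
    is_dmc and (optionally) meth_diff.

    Sites must be sorted by (chrom, pos); rows with NaN p-values are
    ignored.  Returns DMRRecords sorted by (chrom, start).
    """
    required = {"chrom", "pos", "p_value", "is_dmc"}
    if not required <= set(sites.columns):
        raise ValueError(f"sites table needs columns {sorted(required)}")
    chroms = sites["chrom"].to_numpy()
    poss = sites["pos"].to_numpy()
    keys = list(zip(chroms, poss))
    if keys != sorted(keys):
        raise ValueError("sites must be sorted by (chrom, pos)")

    half = window_bp // 2
    have_diff = "meth_diff" in sites.columns
    out = []
    for chrom in pd.unique(chroms):
        sub = sites[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        pval = sub["p_value"].to_numpy(dtype=float)
        dmc = sub["is_dmc"].to_numpy(dtype=bool)
        diff = sub["meth_diff"].to_numpy(dtype=float) if have_diff else np.full(len(sub), np.nan)
        valid = ~np.isnan(pval)

        candidates = []  # (frozenset of positions, criterion)

        # criterion 1: 2 kb window centered on each DMC; needs >= 2 CGs at
        # p <= p_thresh including the DMC itself
        le = valid & (pval <= p_thresh)
        for i in np.flatnonzero(dmc & le):
            in_win = le & (pos >= pos[i] - half) & (pos <= pos[i] + half)
            if in_win.sum() >= 2:
                candidates.append((frozenset(pos[in_win].tolist()), "1"))

        # criterion 2: maximal runs of >= 3 CGs with p < p_thresh and span
        # <= window_bp (sorted two-pointer sweep)
        lt_idx = np.flatnonzero(valid & (pval < p_thresh))
        lt_pos = pos[lt_idx]
        j = 0
        prev_end = -1
        for i in range(len(lt_idx)):
            j = max(j, i)
            while j + 1 < len(lt_idx) and lt_pos[j + 1] - lt_pos[i] <= window_bp:
                j += 1
            if j - i + 1 >= 3 and j > prev_end:
                candidates.append((frozenset(lt_pos[i : j + 1].tolist()), "2"))
                prev_end = j

        # merge candidates sharing any contributing CG
        merged = []  # list of [set, criteria-set]
        for cg_set, crit in candidates:
            cur = set(cg_set)
            crits = {crit}
            rest = []
            for s, c in merged:
                if s & cur:
                    cur |= s
                    crits |= c
                else:
                    rest.append([s, c])
            rest.append([cur, crits])
            merged = rest

        pos_to_diff = dict(zip(pos.tolist(), diff.tolist()))
        for cg_set, crits in merged:
            cg_sorted = sorted(cg_set)
            diffs = [pos_to_diff[p] for p in cg_sorted]
            out.append(
                DMRRecord(
                    chrom=chrom,
                    start=int(cg_sorted[0]),
                    stop=int(cg_sorted[-1]),
                    n_cg=len(cg_sorted),
                    mean_meth_diff=float(np.mean(diffs)),
                    criterion="both" if len(crits) > 1 else crits.pop(),
                    sites=[(chrom, int(p)) for p in cg_sorted],
                )
            )
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def dmrs_to_table(dmrs) -> pd.DataFrame:
    """Tabular DMR export (id, CG count, mean difference, criterion)."""
    return pd.DataFrame(
        {
            "DMR_ID": [d.dmr_id for d in dmrs],
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "stop": [d.stop for d in dmrs],
            "n_cg": [d.n_cg for d in dmrs],
            "mean_meth_diff": [d.mean_meth_diff for d in dmrs],
            "criterion": [d.criterion for d in dmrs],
        }
    )


def dmrs_to_bed(dmrs) -> str:
    lines = [
        f"{d.chrom}\t{d.start - 1}\t{d.stop}\t{d.dmr_id}\t{d.n_cg}\t." for d in dmrs
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Gene association
# ---------------------------------------------------------------------------


@dataclass
class GeneAssociation:
    feature_id: str
    gene_id: str
    signed_distance: int


def annotate(features: pd.DataFrame, genes, window_bp: int = 10000) -> list:
    """Associate features with genes within window_bp of the gene span.

    ``features`` needs columns feature_id, chrom, start, stop (1-based
    inclusive; for a DMC start == stop == pos).  A feature is associated
    with every gene whose extended interval [start - w, end + w] it
    intersects; the distance bound is inclusive (exactly 10 kb counts).
    """
    trees: dict = {}
    for g in genes:
        # half-open tree interval covering the inclusive extended span
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - window_bp, g.end + window_bp + 1, g
        )
    out = []
    for _, row in features.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for iv in sorted(tree.overlap(row["start"], row["stop"] + 1),
                         key=lambda iv: (iv.data.start, iv.data.gene_id)):
            g = iv.data
            out.append(
                GeneAssociation(
                    feature_id=str(row["feature_id"]),
                    gene_id=g.gene_id,
                    signed_distance=_signed_distance(
                        int(row["start"]), int(row["stop"]), g
                    ),
                )
            )
    return out


def _signed_distance(f_start: int, f_stop: int, gene) -> int:
    """0 if the feature intersects the gene body, else strand-aware signed
    bp to the nearer gene edge (negative upstream of TSS, positive
    downstream of TES)."""
    if f_stop >= gene.start and f_start <= gene.end:
        return 0
    if f_stop < gene.start:
        gap = gene.start - f_stop
        upstream = gene.strand != "-"
    else:
        gap = f_start - gene.end
        upstream = gene.strand == "-"
    return -gap if upstream else gap


# ---------------------------------------------------------------------------
# Fisher gene-set enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    set_id: str
    n_hits: int
    n_set: int
    n_foreground: int
    n_background: int
    odds_ratio: float
    p_value: float
    passes: bool


def enrich(
    foreground_genes,
    background_genes,
    gene_sets: dict,
    alpha: float = 0.05,
    min_hits: int = 3,
) -> list:
    """One-sided Fisher exact enrichment of gene sets in the foreground.

    Gene sets are intersected with the background before testing; a set
    passes iff p < alpha AND n_hits >= min_hits.
    """
    fg = set(foreground_genes)
    bg = set(background_genes)
    if not fg <= bg:
        raise ValueError("foreground genes must be a subset of the background")
    out = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & bg
        hits = len(members & fg)
        a = hits
        b = len(fg) - hits
        c = len(members) - hits
        d = len(bg) - len(fg) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        out.append(
            EnrichmentResult(
                set_id=set_id,
                n_hits=hits,
                n_set=len(members),
                n_foreground=len(fg),
                n_background=len(bg),
                odds_ratio=float(odds),
                p_value=float(p),
                passes=bool(p < alpha and hits >= min_hits),
            )
        )
    return out


def read_gmt(path) -> dict:
    """Read gene sets in GMT format (set id, description, genes...)."""
    sets: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
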