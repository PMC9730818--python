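"""Synthetic toy genome with the statistical structure the analysis assumes.

The generator emulates the shape of a Break-seq + ENCODE study on a small
genome (three 10-Mb chromosomes by default, about 1/100 of a human genome):

* genes in four size classes (1-100 / 100-300 / 300-800 / >800 kb) placed
  without overlap, packed toward the left arm of each chromosome with
  chromosome-to-chromosome density differences, producing the gene-density
  gradient that drives the radial (GP-seq-like) score track;
* a designated "expressed" gene subset whose bodies carry H3K36me3-like
  blocks, H3K27me3-like blocks on a subset of silent genes, TSS features at
  gene 5' ends, and CTCF-like sites at a subset of TSSs plus isolated
  intergenic anchor sites;
* one elevated/baseline signal track per feature set and a 1-Mb-binned
  radial score proportional to local gene density;
* three DSB sets (NT / DMSO / APH) of increasing size sharing a spontaneous
  core, with configurable fractions of the induced DSBs planted inside
  mark blocks (f_mark) or at a fixed +/- offset from intergenic CTCF
  anchors (f_ctcf, the bimodal profile signature); everything else is
  uniform background.

Every planted assignment is recorded in a manifest so planted-effect
recovery is measurable.  All randomness flows from one seed through named
substreams; output is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import Genome, GenomicInterval, InputError, IntervalSet
from .context import GeneModel
from .tracks import SignalTrack

# class bounds used for simulated gene lengths; the open-ended >800 kb
# class is capped at 1500 kb so the largest genes still fit a 10-Mb arm
_SIM_CLASS_BOUNDS_KB = ((1, 100), (100, 300), (300, 800), (800, 1500))

CONDITIONS = ("NT", "DMSO", "APH")


@dataclass
class SimConfig:
    n_chroms: int = 3
    chrom_len_bp: int = 10_000_000
    genes_per_class: tuple[int, int, int, int] = (300, 60, 12, 4)
    expressed_fraction: float = 0.4
    mark_coverage_fraction: float = 0.24   # of each expressed gene body; with the
                                           # default gene complement the blocks
                                           # cover ~5% of the genome
    silent_mark_fraction: float = 0.3      # silent genes carrying H3K27me3-like blocks
    ctcf_tss_fraction: float = 0.5         # genes whose TSS carries a CTCF site
    n_intergenic_ctcf: int = 150
    feature_width: int = 200               # TSS / CTCF site width (bp)
    n_dsbs: dict = field(default_factory=lambda: {"NT": 200, "DMSO": 400, "APH": 700})
    shared_core_fraction: float = 0.8      # of NT reappearing in DMSO/APH
    f_mark: float = 0.5                    # induced DSBs planted inside mark blocks
    f_ctcf: float = 0.2                    # induced DSBs planted at +/- offset from CTCF anchors
    ctcf_bimodal_offset: int = 2000
    dsb_len_median: int = 1000             # lognormal length model
    dsb_len_sigma: float = 0.5
    dsb_len_min: int = 100
    dsb_len_max: int = 8000
    signal_high: float = 5.0
    signal_baseline: float = 0.1
    signal_noise_sd: float = 0.5           # per-segment jitter over features
    baseline_noise_sd: float = 0.05        # per-tile jitter elsewhere
    track_tile_bp: int = 10_000            # baseline noise tile size
    gpseq_bin_bp: int = 10_000             # radial score bin; 1/100 of the 1-Mb
                                           # bins used on a full-size genome,
                                           # matching the toy genome's scale
    seed: int = 0

    def __post_init__(self):
        for name in ("expressed_fraction", "mark_coverage_fraction",
                     "silent_mark_fraction", "ctcf_tss_fraction",
                     "shared_core_fraction", "f_mark", "f_ctcf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.f_mark + self.f_ctcf > 1.0:
            raise InputError("f_mark + f_ctcf must not exceed 1")
        for name in ("n_chroms", "chrom_len_bp", "n_intergenic_ctcf",
                     "feature_width", "dsb_len_median", "ctcf_bimodal_offset"):
            if getattr(self, name) < 0 or (name in ("n_chroms", "chrom_len_bp") and getattr(self, name) < 1):
                raise InputError(f"{name} must be positive")
        if any(n < 0 for n in self.genes_per_class):
            raise InputError("gene counts must be nonnegative")
        if any(n < 1 for n in self.n_dsbs.values()):
            raise InputError("DSB counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "genes_per_class" in data:
            data["genes_per_class"] = tuple(data["genes_per_class"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes_per_class"] = list(d["genes_per_class"])
        return d


@dataclass
class SyntheticDataset:
    genome: Genome
    genes: list[GeneModel]
    gene_set: IntervalSet
    features: dict[str, IntervalSet]       # TSS, CTCF, H3K36me3, H3K27me3
    tracks: dict[str, SignalTrack]         # one per feature set
    gpseq: SignalTrack
    dsbs: dict[str, IntervalSet]           # NT, DMSO, APH
    manifest: dict

    def dsb_categories(self, condition: str) -> list[str]:
        """Planted assignment per DSB, in set order."""
        return list(self.manifest["categories"][condition])


# --------------------------------------------------------------------------
# gene layout


def _draw_gene_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lengths = []
    for (lo, hi), n in zip(_SIM_CLASS_BOUNDS_KB, cfg.genes_per_class):
        # log-scale draw skewed toward the class floor (real gene-length
        # distributions are strongly right-skewed within any window)
        b = rng.beta(1.0, 5.0, size=n)
        kb = lo * (hi / lo) ** b
        lengths.append(np.round(kb * 1000).astype(np.int64))
    out = np.concatenate(lengths) if lengths else np.empty(0, dtype=np.int64)
    return np.clip(out, 1000, None)


def _assign_chromosomes(
    cfg: SimConfig, lengths: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gene-density weights decay across chromosomes; overloaded
    chromosomes shed their largest genes to the emptiest one."""
    weights = 0.6 ** np.arange(cfg.n_chroms)
    weights = weights / weights.sum()
    chrom_of = rng.choice(cfg.n_chroms, size=lengths.size, p=weights)
    capacity = 0.85 * cfg.chrom_len_bp
    if lengths.sum() * 1.1 > cfg.n_chroms * cfg.chrom_len_bp:
        raise InputError("gene complement exceeds genome capacity")
    for _ in range(10 * lengths.size + 10):
        totals = np.bincount(chrom_of, weights=lengths, minlength=cfg.n_chroms)
        over = int(np.argmax(totals))
        if totals[over] <= capacity:
            break
        under = int(np.argmin(totals))
        movable = np.flatnonzero(chrom_of == over)
        mover = movable[np.argmax(lengths[movable])]
        chrom_of[mover] = under
    else:
        raise InputError("could not balance genes across chromosomes")
    return chrom_of


def _place_genes(
    cfg: SimConfig, lengths: np.ndarray, chrom_of: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Non-overlapping placement with intergenic gaps that grow along each
    chromosome (quadratic gap weights), producing a left-dense gene-density
    gradient within chromosomes on top of the chromosome-level weights."""
    rows = []
    for c in range(cfg.n_chroms):
        idx = np.flatnonzero(chrom_of == c)
        if idx.size == 0:
            continue
        order = rng.permutation(idx)
        total = int(lengths[order].sum())
        if total + idx.size > cfg.chrom_len_bp:
            raise InputError(f"genes exceed capacity of chromosome chr{c + 1}")
        slack = cfg.chrom_len_bp - total
        w = (np.arange(order.size + 1) + 1.0) ** 2
        gaps = rng.multinomial(slack, w / w.sum())
        pos = int(gaps[0])
        for k, g in enumerate(order):
            length = int(lengths[g])
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"chr{c + 1}", pos, pos + length, f"gene_{g}", strand))
            pos += length + int(gaps[k + 1])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _local_gene_density(
    genes: list[GeneModel], gene_set: IntervalSet, window_bp: int
) -> np.ndarray:
    """Genic-base fraction in a window around each gene's midpoint."""
    out = np.empty(len(genes))
    for i, gene in enumerate(genes):
        iv = gene.interval
        lo = max(0, iv.midpoint - window_bp // 2)
        hi = iv.midpoint + window_bp // 2
        ms, me = gene_set.merged_by_chrom(iv.chrom)
        a = np.searchsorted(me, lo, side="right")
        b = np.searchsorted(ms, hi, side="left")
        covered = 0
        if a < b:
            covered = int((np.minimum(me[a:b], hi) - np.maximum(ms[a:b], lo)).sum())
        out[i] = covered / (hi - lo)
    return out


# --------------------------------------------------------------------------
# features and tracks


def _clip_interval(mid: int, length: int, chrom_len: int) -> tuple[int, int]:
    start = mid - length // 2
    start = max(0, min(start, chrom_len - length))
    return start, start + length


def _feature_track(
    feats: IntervalSet,
    genome: Genome,
    cfg: SimConfig,
    rng: np.random.Generator,
    label: str,
) -> SignalTrack:
    """Whole-genome stepwise track: elevated over feature intervals,
    baseline elsewhere, with per-segment jitter so region means behave
    like real (continuous) coverage rather than a two-valued indicator.
    Baseline stretches are tiled so neighbouring regions decorrelate."""
    segs = []
    for chrom in genome:
        clen = genome[chrom]
        ms, me = feats.merged_by_chrom(chrom)
        tile_edges = np.arange(0, clen + cfg.track_tile_bp, cfg.track_tile_bp)
        tile_edges[-1] = min(tile_edges[-1], clen)
        edges = np.unique(np.concatenate([tile_edges, ms, me, [0, clen]]))
        starts, ends = edges[:-1], edges[1:]
        keep = starts < ends
        starts, ends = starts[keep], ends[keep]
        mids = (starts + ends) // 2
        pos = np.searchsorted(me, mids, side="right")
        inside = (pos < ms.size) & (ms[np.minimum(pos, max(ms.size - 1, 0))] <= mids) if ms.size else np.zeros(mids.size, bool)
        base = np.where(inside, cfg.signal_high, cfg.signal_baseline)
        sd = np.where(inside, cfg.signal_noise_sd, cfg.baseline_noise_sd)
        values = np.clip(base + rng.normal(0.0, 1.0, size=base.size) * sd, 0.0, None)
        segs.extend(
            (chrom, int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)
        )
    return SignalTrack(segs, genome=genome, label=label)


def _gpseq_track(cfg: SimConfig, genome: Genome, gene_set: IntervalSet) -> SignalTrack:
    """Radial score per 1-Mb bin = scaled local genic-base density."""
    fracs = []
    bins = []
    for chrom in genome:
        ms, me = gene_set.merged_by_chrom(chrom)
        for start in range(0, genome[chrom], cfg.gpseq_bin_bp):
            end = min(start + cfg.gpseq_bin_bp, genome[chrom])
            covered = 0
            lo = np.searchsorted(me, start, side="right")
            hi = np.searchsorted(ms, end, side="left")
            if lo < hi:
                covered = int(
                    (np.minimum(me[lo:hi], end) - np.maximum(ms[lo:hi], start)).sum()
                )
            bins.append((chrom, start, end))
            fracs.append(covered / (end - start))
    fracs = np.asarray(fracs)
    top = fracs.max() if fracs.size and fracs.max() > 0 else 1.0
    scores = np.round(0.2 + 0.8 * fracs / top, 4)
    segs = [(c, s, e, v) for (c, s, e), v in zip(bins, scores)]
    return SignalTrack(segs, genome=genome, label="gpseq")


# --------------------------------------------------------------------------
# DSB assembly


def _dsb_lengths(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    raw = rng.lognormal(mean=np.log(cfg.dsb_len_median), sigma=cfg.dsb_len_sigma, size=n)
    return np.clip(np.round(raw).astype(np.int64), cfg.dsb_len_min, cfg.dsb_len_max)


def _uniform_dsbs(cfg, genome, n, rng):
    chroms = list(genome)
    lens = np.array([genome[c] for c in chroms], dtype=float)
    pick = rng.choice(len(chroms), size=n, p=lens / lens.sum())
    sizes = _dsb_lengths(cfg, n, rng)
    rows = []
    for c_idx, L in zip(pick, sizes):
        chrom = chroms[c_idx]
        start = int(rng.integers(0, genome[chrom] - L + 1))
        rows.append((chrom, start, start + int(L)))
    return rows


def _mark_dsbs(cfg, genome, marks: IntervalSet, n, rng):
    starts, ends, chroms = marks.starts, marks.ends, marks.chroms
    w = (ends - starts).astype(float)
    pick = rng.choice(len(marks), size=n, p=w / w.sum())
    sizes = _dsb_lengths(cfg, n, rng)
    rows = []
    for i, L in zip(pick, sizes):
        mid = int(rng.integers(starts[i], ends[i]))
        s, e = _clip_interval(mid, int(L), genome[chroms[i]])
        rows.append((chroms[i], s, e))
    return rows


def _ctcf_dsbs(cfg, genome, anchors: IntervalSet, n, rng):
    centers = (anchors.starts + anchors.ends) // 2
    chroms = anchors.chroms
    pick = rng.integers(0, len(anchors), size=n)
    signs = rng.choice([-1, 1], size=n)
    sizes = _dsb_lengths(cfg, n, rng)
    rows = []
    for i, sign, L in zip(pick, signs, sizes):
        mid = int(centers[i] + sign * cfg.ctcf_bimodal_offset)
        s, e = _clip_interval(mid, int(L), genome[chroms[i]])
        rows.append((chroms[i], s, e))
    return rows


def _induced_components(cfg, genome, marks, ctcf_sites, n_induced, rng):
    n_mark = round(cfg.f_mark * n_induced)
    n_ctcf = round(cfg.f_ctcf * n_induced)
    n_bg = n_induced - n_mark - n_ctcf
    rows, cats = [], []
    if n_mark and len(marks):
        rows += _mark_dsbs(cfg, genome, marks, n_mark, rng)
        cats += ["mark"] * n_mark
    elif n_mark:
        rows += _uniform_dsbs(cfg, genome, n_mark, rng)
        cats += ["background"] * n_mark
    if n_ctcf and len(ctcf_sites):
        rows += _ctcf_dsbs(cfg, genome, ctcf_sites, n_ctcf, rng)
        cats += ["ctcf-offset"] * n_ctcf
    elif n_ctcf:
        rows += _uniform_dsbs(cfg, genome, n_ctcf, rng)
        cats += ["background"] * n_ctcf
    rows += _uniform_dsbs(cfg, genome, n_bg, rng)
    cats += ["background"] * n_bg
    return rows, cats


# --------------------------------------------------------------------------


def generate_dataset(config: Optional[SimConfig] = None) -> SyntheticDataset:
    """Build the full synthetic bundle; deterministic given ``config.seed``."""
    cfg = config or SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    streams = dict(
        zip(
            ("genes", "expression", "features", "tracks", "NT", "DMSO", "APH"),
            (np.random.default_rng(s) for s in root.spawn(7)),
        )
    )
    genome = Genome({f"chr{i + 1}": cfg.chrom_len_bp for i in range(cfg.n_chroms)})

    # ---- genes
    rng = streams["genes"]
    lengths = _draw_gene_lengths(cfg, rng)
    chrom_of = _assign_chromosomes(cfg, lengths, rng)
    gene_df = _place_genes(cfg, lengths, chrom_of, rng)
    gene_df["score"] = None
    gene_set = IntervalSet.from_dataframe(gene_df, genome=genome, label="genes")
    genes = [
        GeneModel(GenomicInterval(r.chrom, r.start, r.end, r.name, None, r.strand), r.name)
        for r in gene_df.itertuples(index=False)
    ]

    # ---- expression assignment: stratified by size class (so the expressed
    # genic mass, hence mark coverage, is stable across seeds) and weighted
    # by local gene density (transcription concentrates in gene-dense
    # clusters, which is what couples the mark to the radial score)
    rng = streams["expression"]
    density = _local_gene_density(genes, gene_set, window_bp=250_000)
    density_by_id = {g.gene_id: d for g, d in zip(genes, density)}
    class_of = np.repeat(np.arange(4), cfg.genes_per_class)
    expressed_ids: set[str] = set()
    for cls in range(4):
        members = np.flatnonzero(class_of == cls)
        n_expr = min(round(cfg.expressed_fraction * members.size), members.size)
        if n_expr == 0:
            continue
        w = np.array(
            [density_by_id.get(f"gene_{g}", 0.0) ** 2 + 1e-6 for g in members]
        )
        chosen = rng.choice(members, size=n_expr, replace=False, p=w / w.sum())
        for g in chosen:
            expressed_ids.add(f"gene_{g}")
    expressed = np.array([g.gene_id in expressed_ids for g in genes])

    # ---- features
    rng = streams["features"]
    w = cfg.feature_width
    tss_rows, ctcf_rows, k36_rows, k27_rows = [], [], [], []
    for i, gene in enumerate(genes):
        iv = gene.interval
        tss = iv.start if iv.strand == "+" else iv.end
        s, e = _clip_interval(tss, w, genome[iv.chrom])
        tss_rows.append((iv.chrom, s, e, f"tss_{gene.gene_id}"))
        if rng.random() < cfg.ctcf_tss_fraction:
            ctcf_rows.append((iv.chrom, s, e, f"ctcf_tss_{gene.gene_id}"))
        block = max(200, round(cfg.mark_coverage_fraction * iv.length))
        bs, be = _clip_interval(iv.midpoint, block, genome[iv.chrom])
        if expressed[i]:
            k36_rows.append((iv.chrom, bs, be, f"k36_{gene.gene_id}"))
        elif rng.random() < cfg.silent_mark_fraction:
            k27_rows.append((iv.chrom, bs, be, f"k27_{gene.gene_id}"))

    # intergenic CTCF anchors: isolated loop-boundary sites in the gene
    # deserts, margin-cleared so their neighbourhoods are unambiguous
    margin = cfg.ctcf_bimodal_offset + cfg.dsb_len_max // 2 + w
    anchor_rows = []
    chrom_names = list(genome)
    chrom_lens = np.array([genome[c] for c in chrom_names], dtype=float)
    gm = {c: gene_set.merged_by_chrom(c) for c in chrom_names}
    attempts = 0
    while len(anchor_rows) < cfg.n_intergenic_ctcf:
        attempts += 1
        if attempts > 200 * max(cfg.n_intergenic_ctcf, 1):
            raise InputError("could not place intergenic CTCF anchors (genome too genic)")
        ci = int(rng.choice(len(chrom_names), p=chrom_lens / chrom_lens.sum()))
        chrom = chrom_names[ci]
        pos = int(rng.integers(margin, genome[chrom] - margin))
        ms, me = gm[chrom]
        p = int(np.searchsorted(me, pos - margin, side="right"))
        if p < ms.size and ms[p] < pos + margin:
            continue
        anchor_rows.append((chrom, pos - w // 2, pos + w - w // 2, f"ctcf_ig_{len(anchor_rows)}"))

    def make_set(rows, label):
        if not rows:
            return IntervalSet(genome=genome, label=label)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        df = df.sort_values(["chrom", "start"], kind="stable")
        return IntervalSet.from_dataframe(df, genome=genome, label=label)

    anchors = make_set(anchor_rows, "CTCF_intergenic")
    features = {
        "TSS": make_set(tss_rows, "TSS"),
        "CTCF": make_set(ctcf_rows + anchor_rows, "CTCF"),
        "H3K36me3": make_set(k36_rows, "H3K36me3"),
        "H3K27me3": make_set(k27_rows, "H3K27me3"),
    }
    tracks = {
        name: _feature_track(fs, genome, cfg, streams["tracks"], name)
        for name, fs in features.items()
    }
    gpseq = _gpseq_track(cfg, genome, gene_set)

    # ---- DSB sets
    marks = features["H3K36me3"]
    categories: dict[str, list[str]] = {}
    dsbs: dict[str, IntervalSet] = {}

    rng = streams["NT"]
    nt_rows = _uniform_dsbs(cfg, genome, cfg.n_dsbs["NT"], rng)
    nt_cats = ["background"] * len(nt_rows)
    categories["NT"] = nt_cats
    dsbs["NT"] = make_dsb_set(nt_rows, nt_cats, "NT", genome)

    n_core = round(cfg.shared_core_fraction * cfg.n_dsbs["NT"])
    for cond in ("DMSO", "APH"):
        rng = streams[cond]
        core_idx = rng.permutation(cfg.n_dsbs["NT"])[:n_core]
        rows = [nt_rows[i] for i in core_idx]
        cats = ["shared-core"] * len(rows)
        n_induced = cfg.n_dsbs[cond] - len(rows)
        if n_induced < 0:
            raise InputError(f"{cond} count smaller than the shared core")
        ind_rows, ind_cats = _induced_components(
            cfg, genome, marks, features["CTCF"], n_induced, rng
        )
        rows += ind_rows
        cats += ind_cats
        categories[cond] = cats
        dsbs[cond] = make_dsb_set(rows, cats, cond, genome)

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_genes": len(genes),
        "n_expressed": int(expressed.sum()),
        "genic_bp": int(gene_set.total_bp()),
        "mark_bp": int(marks.total_bp()),
        "genome_bp": genome.total_bp,
        "feature_counts": {k: len(v) for k, v in features.items()},
        "dsb_counts": {k: len(v) for k, v in dsbs.items()},
        "categories": categories,
    }
    return SyntheticDataset(
        genome=genome,
        genes=genes,
        gene_set=gene_set,
        features=features,
        tracks=tracks,
        gpseq=gpseq,
        dsbs=dsbs,
        manifest=manifest,
    )


def make_dsb_set(rows, cats, condition, genome) -> IntervalSet:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"{condition}_{cat}_{i}" for i, cat in enumerate(cats)]
    return IntervalSet.from_dataframe(df, genome=genome, label=condition)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the bundle as the plain-text formats the analysis reads."""
    import os

    from .io import write_bed, write_bedgraph, write_chrom_sizes

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_chrom_sizes(dataset.genome, p("genome.chrom.sizes"))
    write_bed(dataset.gene_set, p("genes.bed"))
    for name, fs in dataset.features.items():
        write_bed(fs, p(f"feature_{name}.bed"))
    for name, tr in dataset.tracks.items():
        write_bedgraph(tr, p(f"track_{name}.bedgraph"))
    write_bedgraph(dataset.gpseq, p("gpseq.bedgraph"))
    for cond, ds in dataset.dsbs.items():
        write_bed(ds, p(f"dsb_{cond}.bed"))
    with open(p("manifest.json"), "w") as fh:
        json.dump(dataset.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
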