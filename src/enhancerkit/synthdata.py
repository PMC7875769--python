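"""Seeded synthetic epigenomic compendium with planted ground truth.

The generator emulates the inputs of the analysis chain at desk scale:
per-biosample 18-state segmentations, binned -log10 P signal tracks for a
small panel of histone marks (observed and imputed variants of each), a
DHS element index, gene models with expression, biosample metadata and an
association catalog.  Structure is planted so downstream stages have a
parameter-recovery surface:

* enhancers belong to modules; a module is active in a set of tissue
  groups, and each (enhancer, biosample) activity call is a Bernoulli
  draw around that block structure (``module_activity_prob`` inside the
  block, ``leak_prob`` outside);
* each gene's expression is driven by the H3K27ac amplitude of one host
  enhancer plus Gaussian noise, defining true enhancer-gene links;
* each trait's lead SNPs are planted within 2.5 kb of midpoints of
  enhancers active in the trait's tissue group;
* label swaps between tracks can be planted for the QC detectors.

Signal model: active bins draw ``2 + Gamma(shape=2, scale=1.5)``,
inactive bins draw an Exponential(mean 0.5) truncated below the
binarization cutoff of 2, so that activity-label noise is governed
solely by ``leak_prob`` and not by the amplitude tails.  Observed and
imputed tracks share the underlying amplitude and differ by independent
Gaussian noise of sd ``track_noise_sd`` (clipped at 0).

Determinism: one RNG stream per artifact class (layout, activity,
signal, expression, catalog, swaps), each derived from the master seed
with a fixed offset, so e.g. changing ``n_traits`` cannot perturb the
signal tracks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tracks import SignalTrack, write_bed, write_tsv

ENHANCER_STATES = ("E7", "E8", "E9", "E10", "E11", "E15")
PROMOTER_STATES = ("E1", "E2", "E3", "E4", "E14")
QUIESCENT_STATE = "E18"
BODY_STATE = "E5"
HET_STATE = "E17"

DEFAULT_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K36me3", "H3K9me3")

#: Marks grouped by the biology they track; planted antibody swaps are
#: drawn across families so that they are detectable in principle.
MARK_FAMILY = {
    "H3K27ac": "active",
    "H3K4me1": "active",
    "H3K4me2": "active",
    "H3K4me3": "active",
    "H3K9ac": "active",
    "H3K36me3": "transcription",
    "H3K9me3": "repressive",
    "H3K27me3": "repressive",
}

TISSUE_NAMES = (
    "heart", "lung", "brain", "liver", "kidney", "muscle",
    "blood", "skin", "gut", "pancreas", "spleen", "thymus",
)

# RNG stream offsets (fixed; see module docstring)
_STREAMS = {"layout": 0, "activity": 1, "signal": 2, "expression": 3, "catalog": 4, "swaps": 5}

_ENH_STRIDE_BINS = 26  # 5.2 kb at 200-bp bins: midpoints of neighbouring
# elements sit farther apart than twice the 2.5-kb SNP-overlap radius.
_ENH_FIRST_BIN = 10
_GENE_OFFSET_BINS = 3
_BODY_BINS = 3
_SHARED_BIN_FRAC = 0.01
_GROUP_BIN_FRAC = 0.005


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic compendium.

    Defaults define the reference study conditions used throughout the
    test-suite: 6 modules x 200 enhancers over 40 biosamples in 5 tissue
    groups, 200-bp bins, 2% activity leak.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length_bp: int = 1_638_400
    bin_bp: int = 200
    n_tissue_groups: int = 5
    samples_per_group: int = 8
    n_modules: int = 6
    enhancers_per_module: int = 200
    module_activity_prob: float = 0.9
    leak_prob: float = 0.02
    broad_module_fraction: float = 0.125
    n_genes: int = 120
    link_window_bp: int = 1_000_000
    expression_noise_sd: float = 0.5
    n_traits: int = 20
    lead_snps_per_trait: int = 30
    planted_snp_fraction: float = 0.8
    background_snp_count: int = 300
    n_swapped_tracks: int = 0
    marks: tuple[str, ...] = DEFAULT_MARKS
    track_noise_sd: float = 0.25
    broad_group_fraction: float = 0.77

    def __post_init__(self) -> None:
        for name in ("module_activity_prob", "leak_prob", "broad_module_fraction",
                     "planted_snp_fraction", "broad_group_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.chrom_length_bp % self.bin_bp != 0:
            raise ValueError("bin_bp must divide chrom_length_bp")
        if self.n_modules < self.n_tissue_groups:
            raise ValueError("n_modules must be >= n_tissue_groups")
        if self.expression_noise_sd < 0 or self.track_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_tissue_groups > len(TISSUE_NAMES):
            raise ValueError(f"at most {len(TISSUE_NAMES)} tissue groups supported")

    @property
    def bins_per_chrom(self) -> int:
        return self.chrom_length_bp // self.bin_bp

    @property
    def chroms(self) -> list[str]:
        return [f"chrS{i + 1:02d}" for i in range(self.n_chromosomes)]

    @property
    def n_samples(self) -> int:
        return self.n_tissue_groups * self.samples_per_group

    @property
    def n_enhancers(self) -> int:
        return self.n_modules * self.enhancers_per_module

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


@dataclass
class GroundTruth:
    """Planted structure of a synthetic compendium."""

    module_assignment: pd.Series          # enhancer id -> module index
    module_activity: dict[int, frozenset] # module -> biosample ids
    module_groups: dict[int, tuple]       # module -> tissue groups
    true_links: list[tuple]               # (enhancer id, gene id, frozenset of samples)
    trait_tissue: dict[str, tuple]        # trait -> tissue groups
    planted_snps: dict[str, pd.DataFrame] = field(default_factory=dict)
    swapped_pairs: list[dict] = field(default_factory=list)
    # supporting tables (not part of the planted contract, but needed to
    # evaluate it): enhancer/DHS geometry and the realized activity draws
    enhancers: pd.DataFrame | None = None          # chrom,start,end,id,module,state
    activity: pd.DataFrame | None = None           # enhancer x sample, realized 0/1
    sample_groups: pd.Series | None = None
    chrom_sizes: dict[str, int] = field(default_factory=dict)


@dataclass
class Compendium:
    """In-memory synthetic compendium."""

    config: SynthConfig
    metadata: pd.DataFrame
    dhs: pd.DataFrame                      # chrom,start,end,name (incl. promoter elements)
    segmentations: dict[str, pd.DataFrame]
    observed: dict[tuple, SignalTrack]     # (sample, mark) -> track
    imputed: dict[tuple, SignalTrack]
    tss: pd.DataFrame                      # gene,chrom,pos
    expression: pd.DataFrame               # genes x samples (log2 FPKM scale)
    truth: GroundTruth


def _truncated_exp_below(rng: np.random.Generator, size: int, mean: float = 0.5,
                         upper: float = 2.0) -> np.ndarray:
    """Exponential(mean) conditioned on being < upper."""
    rate = 1.0 / mean
    cap = 1.0 - np.exp(-rate * upper)
    u = rng.random(size) * cap
    return -np.log1p(-u) / rate


def _layout(config: SynthConfig, rng: np.random.Generator):
    """Place enhancer slots, genes and mark-specific domains on the genome."""
    bpc = config.bins_per_chrom
    slots = []  # (chrom index, center bin)
    for ci in range(config.n_chromosomes):
        b = _ENH_FIRST_BIN
        while b + _GENE_OFFSET_BINS + _BODY_BINS + 1 < bpc:
            slots.append((ci, b))
            b += _ENH_STRIDE_BINS
    if config.n_enhancers > len(slots):
        raise ValueError(
            f"{config.n_enhancers} enhancers requested but only {len(slots)} "
            f"slots available on this genome"
        )
    order = rng.permutation(len(slots))
    enh_slots = [slots[i] for i in order[: config.n_enhancers]]
    return enh_slots


def generate_compendium(config: SynthConfig) -> Compendium:
    """Generate a full compendium; identical config implies identical output."""
    rng_layout = config.rng("layout")
    rng_act = config.rng("activity")
    rng_sig = config.rng("signal")
    rng_expr = config.rng("expression")

    chroms = config.chroms
    bpc = config.bins_per_chrom
    n_bins = config.n_chromosomes * bpc
    groups = list(TISSUE_NAMES[: config.n_tissue_groups])

    # ---- biosamples -----------------------------------------------------
    samples, sample_group = [], []
    for gi, g in enumerate(groups):
        for j in range(config.samples_per_group):
            samples.append(f"BS{gi * config.samples_per_group + j:03d}")
            sample_group.append(g)
    metadata = pd.DataFrame({
        "sample": samples,
        "tissue_group": sample_group,
        "life_stage": [("embryonic", "adult")[i % 2] for i in range(len(samples))],
        "sex": [("female", "male")[(i // 2) % 2] for i in range(len(samples))],
        "type": ["tissue"] * len(samples),
    })
    sample_groups = pd.Series(sample_group, index=samples, name="tissue_group")

    # ---- enhancer geometry and modules ----------------------------------
    enh_slots = _layout(config, rng_layout)
    n_enh = config.n_enhancers
    enh_ids = [f"DHS{i:06d}" for i in range(n_enh)]
    enh_chrom_i = np.array([s[0] for s in enh_slots])
    enh_bin = np.array([s[1] for s in enh_slots])
    enh_gbin = enh_chrom_i * bpc + enh_bin
    module_of = np.arange(n_enh) // config.enhancers_per_module
    enh_state = np.array(ENHANCER_STATES)[rng_layout.integers(0, len(ENHANCER_STATES), n_enh)]

    n_broad = int(round(config.broad_module_fraction * config.n_modules))
    n_groups_broad = int(np.ceil(config.broad_group_fraction * len(groups)))
    module_groups: dict[int, tuple] = {}
    spec_modules = list(range(config.n_modules - n_broad))
    for i, m in enumerate(spec_modules):
        module_groups[m] = (groups[i % len(groups)],)
    for m in range(config.n_modules - n_broad, config.n_modules):
        chosen = rng_layout.choice(len(groups), size=n_groups_broad, replace=False)
        module_groups[m] = tuple(groups[i] for i in sorted(chosen))
    module_activity = {
        m: frozenset(s for s, g in zip(samples, sample_group) if g in module_groups[m])
        for m in module_groups
    }

    # realized per-(enhancer, sample) activity
    in_block = np.zeros((n_enh, len(samples)), dtype=bool)
    for m, grps in module_groups.items():
        cols = np.array([g in grps for g in sample_group])
        in_block[module_of == m] |= cols[None, :]
    u = rng_act.random((n_enh, len(samples)))
    a_true = np.where(in_block, u < config.module_activity_prob, u < config.leak_prob)

    # ---- genes and true links -------------------------------------------
    if config.n_genes > n_enh:
        raise ValueError("n_genes exceeds number of enhancers available as link hosts")
    host = rng_layout.choice(n_enh, size=config.n_genes, replace=False)
    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    gene_gbin = enh_gbin[host] + _GENE_OFFSET_BINS
    gene_chrom_i = enh_chrom_i[host]
    tss_pos = (gene_gbin - gene_chrom_i * bpc) * config.bin_bp + config.bin_bp // 2
    true_links = [
        (enh_ids[e], g, frozenset(np.array(samples)[a_true[e]]))
        for e, g in zip(host, gene_ids)
    ]

    # ---- mark-specific background domains -------------------------------
    reserved = np.zeros(n_bins, dtype=bool)
    for off in (-1, 0, 1):
        reserved[enh_gbin + off] = True
    reserved[gene_gbin] = True
    for off in range(1, _BODY_BINS + 1):
        reserved[gene_gbin + off] = True
    free = np.flatnonzero(~reserved)
    free = free[rng_layout.permutation(len(free))]
    n_shared = max(1, int(_SHARED_BIN_FRAC * n_bins))
    n_group = max(1, int(_GROUP_BIN_FRAC * n_bins))
    cursor = 0
    mark_shared: dict[str, np.ndarray] = {}
    mark_group: dict[tuple, np.ndarray] = {}
    for mark in config.marks:
        mark_shared[mark] = np.sort(free[cursor:cursor + n_shared]); cursor += n_shared
        for g in groups:
            mark_group[(mark, g)] = np.sort(free[cursor:cursor + n_group]); cursor += n_group
    if cursor > len(free):
        raise ValueError("genome too small for the requested mark domains")

    body_gbins = np.concatenate([gene_gbin + off for off in range(1, _BODY_BINS + 1)])

    # ---- signal tracks ---------------------------------------------------
    def split_chroms(vec: np.ndarray) -> dict[str, np.ndarray]:
        return {c: vec[ci * bpc:(ci + 1) * bpc].copy() for ci, c in enumerate(chroms)}

    observed: dict[tuple, SignalTrack] = {}
    imputed: dict[tuple, SignalTrack] = {}
    amp27 = np.zeros((n_enh, len(samples)))
    peak_offsets = np.array([-1, 0, 1])
    for si, s in enumerate(samples):
        g = sample_group[si]
        for mark in config.marks:
            amp = _truncated_exp_below(rng_sig, n_bins)
            if mark in ("H3K27ac", "H3K4me1"):
                act_e = np.flatnonzero(a_true[:, si])
                pe = 2.0 + rng_sig.gamma(2.0, 1.5, size=len(act_e))
                for off in peak_offsets:
                    amp[enh_gbin[act_e] + off] = pe
                if mark == "H3K27ac":
                    amp27[act_e, si] = pe
                    amp27[~a_true[:, si], si] = amp[enh_gbin[~a_true[:, si]]]
                    amp[gene_gbin] = 2.0 + rng_sig.gamma(2.0, 1.5, size=len(gene_gbin))
            elif mark == "H3K4me3":
                amp[gene_gbin] = 2.0 + rng_sig.gamma(2.0, 1.5, size=len(gene_gbin))
            elif mark == "H3K36me3":
                amp[body_gbins] = 2.0 + rng_sig.gamma(2.0, 1.5, size=len(body_gbins))
            dom = np.concatenate([mark_shared[mark], mark_group[(mark, g)]])
            amp[dom] = 2.0 + rng_sig.gamma(2.0, 1.5, size=len(dom))
            for store in (observed, imputed):
                noisy = amp
                if config.track_noise_sd > 0:
                    noisy = np.clip(amp + rng_sig.normal(0.0, config.track_noise_sd, n_bins), 0.0, None)
                store[(s, mark)] = SignalTrack(s, mark, config.bin_bp, split_chroms(noisy))

    # ---- segmentations ---------------------------------------------------
    segmentations: dict[str, pd.DataFrame] = {}
    for si, s in enumerate(samples):
        states = np.full(n_bins, QUIESCENT_STATE, dtype=object)
        act_e = np.flatnonzero(a_true[:, si])
        for off in peak_offsets:
            states[enh_gbin[act_e] + off] = enh_state[act_e]
        states[gene_gbin] = "E1"
        states[body_gbins] = BODY_STATE
        g = sample_group[si]
        if "H3K9me3" in config.marks:
            states[mark_group[("H3K9me3", g)]] = HET_STATE
        rows = []
        for ci, c in enumerate(chroms):
            sc = states[ci * bpc:(ci + 1) * bpc]
            change = np.flatnonzero(sc[1:] != sc[:-1]) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [bpc]])
            for a, b in zip(starts, ends):
                rows.append((c, a * config.bin_bp, b * config.bin_bp, sc[a]))
        segmentations[s] = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])

    # ---- DHS index (enhancer elements + promoter elements) ---------------
    dhs_rows = []
    for i in range(n_enh):
        c = chroms[enh_chrom_i[i]]
        start = enh_bin[i] * config.bin_bp
        dhs_rows.append((c, start, start + config.bin_bp, enh_ids[i]))
    for i in range(config.n_genes):
        c = chroms[gene_chrom_i[i]]
        start = (gene_gbin[i] - gene_chrom_i[i] * bpc) * config.bin_bp
        dhs_rows.append((c, start, start + config.bin_bp, f"PRM{i:04d}"))
    dhs = pd.DataFrame(dhs_rows, columns=["chrom", "start", "end", "name"])
    dhs = dhs.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    # ---- expression -------------------------------------------------------
    expr = amp27[host, :] + rng_expr.normal(0.0, config.expression_noise_sd,
                                            size=(config.n_genes, len(samples)))
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)
    tss = pd.DataFrame({
        "gene": gene_ids,
        "chrom": [chroms[c] for c in gene_chrom_i],
        "pos": tss_pos,
    })

    enh_table = pd.DataFrame({
        "chrom": [chroms[c] for c in enh_chrom_i],
        "start": enh_bin * config.bin_bp,
        "end": enh_bin * config.bin_bp + config.bin_bp,
        "id": enh_ids,
        "module": module_of,
        "state": enh_state,
    })
    truth = GroundTruth(
        module_assignment=pd.Series(module_of, index=enh_ids, name="module"),
        module_activity=module_activity,
        module_groups=module_groups,
        true_links=true_links,
        trait_tissue={},
        enhancers=enh_table,
        activity=pd.DataFrame(a_true.astype(np.int8), index=enh_ids, columns=samples),
        sample_groups=sample_groups,
        chrom_sizes={c: config.chrom_length_bp for c in chroms},
    )
    return Compendium(
        config=config, metadata=metadata, dhs=dhs, segmentations=segmentations,
        observed=observed, imputed=imputed, tss=tss, expression=expression, truth=truth,
    )


def generate_gwas_catalog(config: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Generate an association catalog with planted trait-tissue structure.

    Each trait is assigned one tissue group (round-robin) and receives
    ``lead_snps_per_trait`` associations with log-uniform p-values in
    [1e-30, 5e-8]; a ``planted_snp_fraction`` of them land within 2.5 kb
    of midpoints of enhancers whose module is active in that group, the
    rest (and all extra background studies) are uniform over the genome.
    Sample sizes are drawn >= 10,000 so power filters pass by design.
    """
    if truth.enhancers is None:
        raise ValueError("compendium must be generated before the catalog")
    rng = config.rng("catalog")
    groups = list(TISSUE_NAMES[: config.n_tissue_groups])
    chroms = config.chroms
    clen = config.chrom_length_bp
    enh = truth.enhancers
    mid1 = (enh["start"].to_numpy() + enh["end"].to_numpy()) // 2 + 1  # 1-based midpoint

    def logu_pvals(n):
        lo, hi = np.log10(1e-30), np.log10(5e-8)
        return 10.0 ** (lo + (hi - lo) * rng.random(n))

    rows = []
    trait_tissue: dict[str, tuple] = {}
    planted: dict[str, pd.DataFrame] = {}
    for ti in range(config.n_traits):
        trait = f"trait{ti:03d}"
        group = groups[ti % len(groups)]
        trait_tissue[trait] = (group,)
        active_modules = [m for m, gs in truth.module_groups.items() if group in gs]
        hosts = np.flatnonzero(enh["module"].isin(active_modules).to_numpy())
        if len(hosts) == 0:
            raise ValueError(f"tissue group {group} has no enhancers to host SNPs")
        n_plant = int(round(config.planted_snp_fraction * config.lead_snps_per_trait))
        chosen = rng.choice(hosts, size=n_plant, replace=n_plant > len(hosts))
        offs = rng.integers(-2500, 2501, size=n_plant)
        ppos = np.clip(mid1[chosen] + offs, 1, clen)
        pchrom = enh["chrom"].to_numpy()[chosen]
        n_bg = config.lead_snps_per_trait - n_plant
        bchrom = np.array(chroms)[rng.integers(0, len(chroms), n_bg)]
        bpos = rng.integers(1, clen + 1, size=n_bg)
        allchrom = np.concatenate([pchrom, bchrom])
        allpos = np.concatenate([ppos, bpos])
        pv = logu_pvals(config.lead_snps_per_trait)
        size = int(rng.integers(10_000, 500_000))
        pmid = 30_000_000 + ti
        for c, p, q in zip(allchrom, allpos, pv):
            rows.append((trait, pmid, c, int(p), float(q), size))
        planted[trait] = pd.DataFrame({
            "chrom": pchrom, "pos": ppos.astype(np.int64),
            "enhancer": enh["id"].to_numpy()[chosen],
        })

    n_bg_traits = config.background_snp_count // max(1, config.lead_snps_per_trait)
    for bi in range(n_bg_traits):
        trait = f"bgtrait{bi:03d}"
        bchrom = np.array(chroms)[rng.integers(0, len(chroms), config.lead_snps_per_trait)]
        bpos = rng.integers(1, clen + 1, size=config.lead_snps_per_trait)
        pv = logu_pvals(config.lead_snps_per_trait)
        size = int(rng.integers(10_000, 500_000))
        pmid = 40_000_000 + bi
        for c, p, q in zip(bchrom, bpos, pv):
            rows.append((trait, pmid, c, int(p), float(q), size))

    truth.trait_tissue = trait_tissue
    truth.planted_snps = planted
    return pd.DataFrame(
        rows, columns=["trait", "pubmed_id", "chrom", "pos", "pvalue", "sample_size"]
    )


def plant_swaps(
    tracks: dict[tuple, SignalTrack],
    n_swapped_tracks: int,
    seed: int,
    kind: str = "sample",
    sample_groups: pd.Series | None = None,
) -> tuple[dict[tuple, SignalTrack], list[dict]]:
    """Exchange the labels of randomly chosen track pairs.

    ``kind='sample'`` exchanges same-mark tracks of two biosamples from
    different tissue groups (when ``sample_groups`` is given);
    ``kind='antibody'`` exchanges two marks of one biosample drawn from
    different mark families, so the planted swap is biologically
    distinguishable.  ``n_swapped_tracks`` counts relabeled tracks and
    must be even.  Returns the relabeled track dict and a registry of
    the planted truth.
    """
    if n_swapped_tracks % 2 != 0:
        raise ValueError("n_swapped_tracks must be even (swaps come in pairs)")
    marks = sorted({m for (_, m) in tracks})
    for m in marks:
        if sum(1 for (_, mm) in tracks if mm == m) < 2:
            raise ValueError(f"need at least 2 tracks per mark, mark {m} has fewer")
    out = {k: SignalTrack(k[0], k[1], t.bin_bp, dict(t.data)) for k, t in tracks.items()}
    registry: list[dict] = []
    if n_swapped_tracks == 0:
        return out, registry
    rng = np.random.default_rng([_STREAMS["swaps"], seed])
    used: set = set()
    n_pairs = n_swapped_tracks // 2
    keys = sorted(tracks)
    for _ in range(n_pairs):
        candidates = []
        if kind == "sample":
            for i, ka in enumerate(keys):
                for kb in keys[i + 1:]:
                    if ka[1] != kb[1] or ka in used or kb in used or ka[0] == kb[0]:
                        continue
                    if sample_groups is not None and sample_groups[ka[0]] == sample_groups[kb[0]]:
                        continue
                    candidates.append((ka, kb))
        elif kind == "antibody":
            for i, ka in enumerate(keys):
                for kb in keys[i + 1:]:
                    if ka[0] != kb[0] or ka in used or kb in used or ka[1] == kb[1]:
                        continue
                    fa = MARK_FAMILY.get(ka[1]), MARK_FAMILY.get(kb[1])
                    if fa[0] is not None and fa[0] == fa[1]:
                        continue
                    candidates.append((ka, kb))
        else:
            raise ValueError(f"unknown swap kind: {kind}")
        if not candidates:
            raise ValueError("not enough unswapped track pairs available")
        ka, kb = candidates[rng.integers(0, len(candidates))]
        used.update((ka, kb))
        out[ka].data, out[kb].data = out[kb].data, out[ka].data
        registry.append({"kind": f"{kind}_swap", "track_a": f"{ka[0]}:{ka[1]}",
                         "track_b": f"{kb[0]}:{kb[1]}"})
    return out, registry


# --------------------------------------------------------------------------
# Emission


def write_compendium(comp: Compendium, outdir: str | Path,
                     catalog: pd.DataFrame | None = None) -> list[Path]:
    """Write all artifacts as plain-text files; byte-deterministic."""
    outdir = Path(outdir)
    (outdir / "segmentations").mkdir(parents=True, exist_ok=True)
    (outdir / "signal" / "observed").mkdir(parents=True, exist_ok=True)
    (outdir / "signal" / "imputed").mkdir(parents=True, exist_ok=True)
    written = []

    def emit(path, fn):
        fn(path)
        written.append(path)

    emit(outdir / "metadata.tsv", lambda p: write_tsv(comp.metadata, p))
    emit(outdir / "dhs_index.bed", lambda p: write_bed(comp.dhs, p))
    emit(outdir / "gene_tss.bed", lambda p: write_bed(
        comp.tss.assign(start=comp.tss["pos"], end=comp.tss["pos"] + 1, name=comp.tss["gene"]), p))
    emit(outdir / "expression.tsv", lambda p: write_tsv(comp.expression, p, index=True))
    for s in sorted(comp.segmentations):
        emit(outdir / "segmentations" / f"{s}.bed",
             lambda p, s=s: comp.segmentations[s].to_csv(p, sep="\t", header=False, index=False))
    for (s, m) in sorted(comp.observed):
        emit(outdir / "signal" / "observed" / f"{s}_{m}.bedgraph",
             lambda p, k=(s, m): _fast_bedgraph(comp.observed[k], p))
    for (s, m) in sorted(comp.imputed):
        emit(outdir / "signal" / "imputed" / f"{s}_{m}.bedgraph",
             lambda p, k=(s, m): _fast_bedgraph(comp.imputed[k], p))
    if catalog is not None:
        emit(outdir / "gwas_catalog.tsv", lambda p: write_tsv(catalog, p))
    gt = {
        "module_assignment": comp.truth.module_assignment.to_dict(),
        "module_groups": {str(k): list(v) for k, v in comp.truth.module_groups.items()},
        "trait_tissue": {k: list(v) for k, v in comp.truth.trait_tissue.items()},
        "true_links": [[e, g, sorted(ss)] for e, g, ss in comp.truth.true_links],
        "swapped_pairs": comp.truth.swapped_pairs,
    }
    path = outdir / "ground_truth.json"
    with open(path, "w") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)
    written.append(path)
    return written


def _fast_bedgraph(track: SignalTrack, path: Path) -> None:
    frames = []
    for chrom in track.chroms:
        v = track.data[chrom]
        n = len(v)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": np.arange(n, dtype=np.int64) * track.bin_bp,
            "end": (np.arange(n, dtype=np.int64) + 1) * track.bin_bp,
            "value": np.round(v, 4),
        }))
    pd.concat(frames).to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")
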