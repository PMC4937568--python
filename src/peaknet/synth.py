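"""Synthetic multi-cell peak compendium with a known regulatory grammar.

Every site is an i.i.d. background sequence into which motif instances
(sampled from position weight matrices, either strand) are planted
within a central region.  A site is accessible in a cell type iff its
sequence contains at least one motif cognate to that cell; labels are
then flipped with a small noise probability.  Because the generator
records every plant, downstream analyses — filter/motif recovery,
saturation mutagenesis localization, causal-versus-bystander SNP
scoring — can be checked against ground truth.

To keep labels and sequence content exactly equivalent (so a perfect
sequence model can in principle reach the noise ceiling), backgrounds
are rejection-sampled to contain no motif match: a short motif would
otherwise arise by chance in a sizeable fraction of 600-bp windows,
divorcing labels from content.  Motif PWMs put probability one on
consensus columns and split degenerate (IUPAC S/W) columns evenly, so a
PWM sample is precisely a word the scanner recognizes; after planting,
sites are redrawn in the rare event a junction creates a spurious match.

The default grammar uses three motifs echoing well-known accessibility
drivers: an AP-1-like TGASTCA 7-mer, a CTCF-like 19-mer and a GC-rich
8-mer, wired to four pseudo cell types (one cell responds to two motifs
so the grammar is not a pure one-motif-one-cell code).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .interpret import information_content
from .sequence import BASES, encode_indices

logger = logging.getLogger(__name__)

_PAD = 400        # background padding at each end of the synthetic genome
_SPACER = 200     # background spacer between adjacent sites


def _pwm_from_pattern(pattern):
    """PWM from an IUPAC pattern: listed bases share the column evenly."""
    iupac = {"A": "A", "C": "C", "G": "G", "T": "T",
             "S": "CG", "W": "AT", "R": "AG", "Y": "CT", "N": "ACGT"}
    pwm = np.zeros((len(pattern), 4))
    for i, code in enumerate(pattern):
        allowed = iupac[code]
        for b in allowed:
            pwm[i, BASES.index(b)] = 1.0 / len(allowed)
    return pwm


@dataclass(frozen=True)
class Motif:
    name: str
    pwm: np.ndarray             # (W, 4) rows sum to 1
    cells: tuple                # cognate cell indices
    plant_prob: float

    @property
    def width(self):
        return self.pwm.shape[0]

    @property
    def consensus(self):
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))

    @property
    def ic(self):
        return information_content(self.pwm)

    def rc_pwm(self):
        return self.pwm[::-1, ::-1]

    def sample_indices(self, rng, strand="+"):
        pwm = self.pwm if strand == "+" else self.rc_pwm()
        return np.array([rng.choice(4, p=row) for row in pwm])

    def match_positions(self, base_indices):
        """Start positions (either strand) where the motif matches a site.

        ``base_indices`` is a 1-D array of base indices; a window matches
        when every position holds a base the PWM allows (probability > 0).
        """
        seq = np.asarray(base_indices)
        out = []
        for allowed in (self.pwm > 0, self.rc_pwm() > 0):
            W = allowed.shape[0]
            if len(seq) < W:
                continue
            win = np.lib.stride_tricks.sliding_window_view(seq, W)
            ok = allowed[np.arange(W), win].all(axis=1)
            out.append(np.flatnonzero(ok))
        return np.unique(np.concatenate(out)) if out else np.array([], dtype=int)

    def present(self, base_indices) -> bool:
        return self.match_positions(base_indices).size > 0


def default_motifs():
    return (
        Motif("AP1_like", _pwm_from_pattern("TGASTCA"), (0, 3), 0.35),
        Motif("CTCF_like", _pwm_from_pattern("TGGCCASCAGGWGGCGCTA"), (1, 3), 0.35),
        Motif("GC_rich", _pwm_from_pattern("GGGGCGGG"), (2,), 0.35),
    )


@dataclass(frozen=True)
class GrammarConfig:
    n_cells: int = 4
    n_sites: int = 10_000
    seq_length: int = 600
    background_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    motifs: tuple = field(default_factory=default_motifs)
    plant_region: tuple | None = None  # defaults to the central half
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.plant_region is None:
            object.__setattr__(self, "plant_region",
                               (self.seq_length // 4, 3 * self.seq_length // 4))
        lo, hi = self.plant_region
        if not (0 <= lo < hi <= self.seq_length):
            raise ValueError("plant_region must lie within the sequence")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must be a probability")
        if abs(sum(self.background_probs) - 1.0) > 1e-9:
            raise ValueError("background_probs must sum to 1")
        for m in self.motifs:
            if m.width > hi - lo:
                raise ValueError(f"motif {m.name} wider than the plant region")
            if any(c >= self.n_cells for c in m.cells):
                raise ValueError(f"motif {m.name} names a cell >= n_cells")


@dataclass(frozen=True)
class Plant:
    motif_id: int
    start: int      # within-site coordinate
    strand: str


@dataclass
class SyntheticDataset:
    """Sequences, noisy activity labels and full ground truth."""

    config: GrammarConfig
    base_indices: np.ndarray      # (N, L) values 0..3
    activity: np.ndarray          # (N, T) noisy labels
    clean_activity: np.ndarray    # (N, T) pre-noise labels
    plants: list                  # list of list[Plant]

    @property
    def n_sites(self):
        return self.base_indices.shape[0]

    @property
    def sequences(self):
        return ["".join(BASES[b] for b in row) for row in self.base_indices]

    def encoded(self, dtype=np.float32):
        return encode_indices(self.base_indices, dtype=dtype)

    def site_offset(self, i):
        """Start of site ``i`` on the concatenated synthetic genome."""
        return _PAD + i * (self.config.seq_length + _SPACER)

    def genome(self, seed_pad=None):
        """The synthetic genome: padded, spacer-separated concatenation.

        Pads and spacers are background sampled from a generator derived
        from the dataset seed, so the genome is reproducible.
        """
        cfg = self.config
        rng = np.random.default_rng((cfg.seed, 915) if seed_pad is None else seed_pad)
        p = np.asarray(cfg.background_probs)
        chunks = [self._bg(rng, _PAD, p)]
        for i in range(self.n_sites):
            if i:
                chunks.append(self._bg(rng, _SPACER, p))
            chunks.append("".join(BASES[b] for b in self.base_indices[i]))
        chunks.append(self._bg(rng, _PAD, p))
        return "".join(chunks)

    def _bg(self, rng, n, p):
        # pads and spacers are motif-free too, like site backgrounds
        for _ in range(100):
            draw = rng.choice(4, size=n, p=p)
            if not any(m.present(draw) for m in self.config.motifs):
                return "".join(BASES[b] for b in draw)
        raise RuntimeError("could not draw a motif-free spacer")

    def footprint_mask(self, i):
        """Boolean (L,) mask of planted positions in site ``i``."""
        mask = np.zeros(self.config.seq_length, dtype=bool)
        for pl in self.plants[i]:
            mask[pl.start : pl.start + self.config.motifs[pl.motif_id].width] = True
        return mask


def _spurious_match(base_row, motifs, plants):
    """True if any motif matches the site outside its own plant records."""
    for mid, motif in enumerate(motifs):
        own = {p.start for p in plants if p.motif_id == mid}
        if set(motif.match_positions(base_row).tolist()) - own:
            return True
    return False


def _draw_site(rng, cfg):
    """One site: motif-free background, then plants; redrawn on collisions."""
    L = cfg.seq_length
    bg = np.asarray(cfg.background_probs)
    lo, hi = cfg.plant_region
    for _ in range(60):
        base = rng.choice(4, size=L, p=bg).astype(np.int8)
        if any(m.present(base) for m in cfg.motifs):
            continue  # background must carry no motif by chance
        occupied = np.zeros(L, dtype=bool)
        plants = []
        for mid, motif in enumerate(cfg.motifs):
            if rng.random() >= motif.plant_prob:
                continue
            for _ in range(20):
                start = int(rng.integers(lo, hi - motif.width + 1))
                if not occupied[start : start + motif.width].any():
                    break
            else:
                logger.warning("no room for %s, plant skipped", motif.name)
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            base[start : start + motif.width] = motif.sample_indices(rng, strand)
            occupied[start : start + motif.width] = True
            plants.append(Plant(mid, start, strand))
        # a plant junction can fabricate an unintended match; redraw then
        if not _spurious_match(base, cfg.motifs, plants):
            return base, plants
    raise RuntimeError("could not draw a grammar-consistent site")


def generate_dataset(config: GrammarConfig | None = None) -> SyntheticDataset:
    """Sample a seed-reproducible dataset from the grammar.

    Site sequences contain a motif exactly where the plant record says
    (backgrounds are motif-free by construction), so the clean activity
    matrix equals both the plant bookkeeping and a content scan.
    """
    cfg = config or GrammarConfig()
    rng = np.random.default_rng(cfg.seed)
    N, L, T = cfg.n_sites, cfg.seq_length, cfg.n_cells
    base = np.empty((N, L), dtype=np.int8)
    clean = np.zeros((N, T), dtype=np.uint8)
    plants_per_site = []
    for i in range(N):
        base[i], plants = _draw_site(rng, cfg)
        for p in plants:
            for c in cfg.motifs[p.motif_id].cells:
                clean[i, c] = 1
        plants_per_site.append(plants)
    noisy = clean.copy()
    if cfg.label_noise > 0:
        flips = rng.random(clean.shape) < cfg.label_noise
        noisy = np.where(flips, 1 - clean, clean).astype(np.uint8)
    return SyntheticDataset(cfg, base, noisy, clean, plants_per_site)


# ---------------------------------------------------------------------------
# labeled variants


@dataclass(frozen=True)
class Variant:
    snp_id: str
    site: int
    pos: int          # within-site coordinate
    ref: str
    alt: str
    causal: bool
    motif_id: int = -1


def generate_variant_set(dataset: SyntheticDataset, n_causal=100, n_bystander=100,
                         seed=0, min_distance=10):
    """Causal SNPs ablate a high-information planted position; bystander
    SNPs hit background >= ``min_distance`` bp from any plant."""
    cfg = dataset.config
    rng = np.random.default_rng(seed)
    planted_sites = [i for i in range(dataset.n_sites) if dataset.plants[i]]
    if len(planted_sites) < n_causal:
        raise ValueError("not enough planted sites for the requested causal SNPs")
    variants = []
    for k, site in enumerate(rng.choice(planted_sites, size=n_causal, replace=False)):
        site = int(site)
        plant = dataset.plants[site][int(rng.integers(len(dataset.plants[site])))]
        motif = cfg.motifs[plant.motif_id]
        # a random full-information column of the (strand-oriented) PWM
        pwm = motif.pwm if plant.strand == "+" else motif.rc_pwm()
        col_ic = (pwm * np.log2(np.maximum(pwm, 1e-12))).sum(axis=1) + 2.0
        top = np.flatnonzero(col_ic >= col_ic.max() - 1e-9)
        col = int(rng.choice(top))
        pos = plant.start + col
        ref_idx = int(dataset.base_indices[site, pos])
        order = np.argsort(pwm[col])  # least probable first
        alt_idx = int(order[0]) if int(order[0]) != ref_idx else int(order[1])
        variants.append(Variant(f"causal_{k:04d}", site, pos, BASES[ref_idx],
                                BASES[alt_idx], True, plant.motif_id))
    for k in range(n_bystander):
        for _ in range(1000):
            site = int(rng.integers(dataset.n_sites))
            pos = int(rng.integers(cfg.seq_length))
            mask = dataset.footprint_mask(site)
            lo = max(0, pos - min_distance)
            hi = min(cfg.seq_length, pos + min_distance + 1)
            if not mask[lo:hi].any():
                break
        else:
            raise RuntimeError("could not place a bystander SNP")
        ref_idx = int(dataset.base_indices[site, pos])
        alt_idx = int(rng.choice([b for b in range(4) if b != ref_idx]))
        variants.append(Variant(f"bystander_{k:04d}", site, pos, BASES[ref_idx],
                                BASES[alt_idx], False))
    return variants


# ---------------------------------------------------------------------------
# writers


def write_fasta(path, name, seq, line_width=60):
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for lo in range(0, len(seq), line_width):
            fh.write(seq[lo : lo + line_width] + "\n")


def write_vcf(path, variants, dataset, contig="chrS"):
    """Write site-relative variants as genome-coordinate VCF (1-based)."""
    genome_len = dataset.site_offset(dataset.n_sites - 1) + dataset.config.seq_length + _PAD
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={genome_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            pos1 = dataset.site_offset(v.site) + v.pos + 1
            fh.write(f"{contig}\t{pos1}\t{v.snp_id}\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def write_dataset(dataset: SyntheticDataset, outdir, variants=None, contig="chrS"):
    """Emit genome FASTA, site/per-cell BEDs, manifest, activity TSV,
    ground-truth JSON and (optionally) a VCF with truth labels."""
    import os

    os.makedirs(outdir, exist_ok=True)
    cfg = dataset.config
    genome = dataset.genome()
    write_fasta(os.path.join(outdir, "genome.fa"), contig, genome)

    L = cfg.seq_length
    cells = [f"cell_{t}" for t in range(cfg.n_cells)]
    with open(os.path.join(outdir, "sites.bed"), "w") as fh:
        for i in range(dataset.n_sites):
            off = dataset.site_offset(i)
            active = ",".join(cells[t] for t in range(cfg.n_cells)
                              if dataset.activity[i, t])
            fh.write(f"{contig}\t{off}\t{off + L}\tsite_{i:06d}\t0\t{active}\n")
    manifest = []
    for t, cell in enumerate(cells):
        bed = os.path.join(outdir, f"{cell}.bed")
        with open(bed, "w") as fh:
            for i in np.flatnonzero(dataset.activity[:, t]):
                off = dataset.site_offset(int(i))
                fh.write(f"{contig}\t{off}\t{off + L}\n")
        manifest.append((cell, bed))
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        for cell, bed in manifest:
            fh.write(f"{cell}\t{bed}\n")
    with open(os.path.join(outdir, "activity.tsv"), "w") as fh:
        fh.write("site\t" + "\t".join(cells) + "\n")
        for i in range(dataset.n_sites):
            row = "\t".join(str(int(v)) for v in dataset.activity[i])
            fh.write(f"site_{i:06d}\t{row}\n")
    truth = {
        "config": {
            "n_cells": cfg.n_cells,
            "n_sites": cfg.n_sites,
            "seq_length": cfg.seq_length,
            "label_noise": cfg.label_noise,
            "seed": cfg.seed,
            "plant_region": list(cfg.plant_region),
            "motifs": [
                {"name": m.name, "consensus": m.consensus, "cells": list(m.cells),
                 "plant_prob": m.plant_prob, "pwm": m.pwm.tolist()}
                for m in cfg.motifs
            ],
        },
        "plants": [
            [{"motif": p.motif_id, "start": p.start, "strand": p.strand}
             for p in site]
            for site in dataset.plants
        ],
    }
    if variants is not None:
        write_vcf(os.path.join(outdir, "variants.vcf"), variants, dataset, contig)
        truth["variants"] = [
            {"id": v.snp_id, "site": v.site, "pos": v.pos, "ref": v.ref,
             "alt": v.alt, "causal": v.causal}
            for v in variants
        ]
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
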