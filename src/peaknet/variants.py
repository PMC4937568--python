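"""Variant scoring: in silico saturation mutagenesis and SAD profiles.

Saturation mutagenesis predicts the accessibility of all 3L single-base
mutants of an L-bp sequence.  Per position, the loss score is the
reference prediction minus the minimum mutant prediction and the gain
score is the maximum mutant prediction minus the reference — positions
with functional motifs show high loss; latent sites show high gain.

A SNP Accessibility Difference (SAD) profile is the per-cell-type
difference in predicted accessibility between a SNP's alternative and
reference alleles, computed on the model-input-length window centered on
the variant.  Only single-nucleotide variants are scored; indels are
skipped with a logged reason, and a reference allele disagreeing with
the genome raises an error naming the position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence import BASES, BASE_INDEX, one_hot_encode

logger = logging.getLogger(__name__)


@dataclass
class SatMutResult:
    """All-mutations effect map of one sequence, for all T cells at once."""

    ref_prediction: np.ndarray   # (T,)
    delta: np.ndarray            # (L, 4, T); reference-base entries are 0
    loss_scores: np.ndarray      # (L, T)
    gain_scores: np.ndarray      # (L, T)
    ref_indices: np.ndarray      # (L,) base index of the reference sequence

    @property
    def length(self):
        return self.delta.shape[0]

    def for_cell(self, t):
        """(delta L x 4, loss L, gain L, ref probability) for one cell."""
        return (self.delta[:, :, t], self.loss_scores[:, t],
                self.gain_scores[:, t], float(self.ref_prediction[t]))


@dataclass
class SADProfile:
    snp_id: str
    ref_allele: str
    alt_allele: str
    per_cell_sad: np.ndarray     # (T,) pred(alt) - pred(ref)

    @property
    def sad_mean(self) -> float:
        return float(self.per_cell_sad.mean())

    @property
    def max_abs_sad(self) -> float:
        return float(np.abs(self.per_cell_sad).max())


def saturation_mutagenesis(network, seq, batch_size=512) -> SatMutResult:
    """Score every possible point mutation of ``seq`` (string or 4 x L one-hot).

    Runs the 3L mutant sequences through the model in eval-mode batches.
    """
    if isinstance(seq, str):
        x = one_hot_encode(seq)
    else:
        x = np.asarray(seq)
    L = x.shape[1]
    if L != network.spec.input_length:
        raise ValueError(
            f"sequence length {L} != model input length {network.spec.input_length}"
        )
    ref_idx = x.argmax(axis=0)
    ref_pred = network.predict(x[None])[0]
    T = ref_pred.shape[0]

    mutants = np.repeat(x[None], 3 * L, axis=0)
    k = 0
    slots = []
    for p in range(L):
        for n in range(4):
            if n == ref_idx[p]:
                continue
            mutants[k, :, p] = 0.0
            mutants[k, n, p] = 1.0
            slots.append((p, n))
            k += 1
    preds = network.predict(mutants, batch_size=batch_size)

    delta = np.zeros((L, 4, T), dtype=float)
    for (p, n), pred in zip(slots, preds):
        delta[p, n] = pred - ref_pred
    mut_preds = delta + ref_pred[None, None, :]
    # exclude the reference-base slot from the order statistics
    masked_min = mut_preds.copy()
    masked_max = mut_preds.copy()
    for p in range(L):
        masked_min[p, ref_idx[p]] = np.inf
        masked_max[p, ref_idx[p]] = -np.inf
    loss = ref_pred[None, :] - masked_min.min(axis=1)
    gain = masked_max.max(axis=1) - ref_pred[None, :]
    return SatMutResult(ref_pred, delta, loss, gain, ref_idx)


def sad_profile(network, genome, chrom, pos, ref, alt, snp_id="snp") -> SADProfile:
    """SAD profile of a single-nucleotide variant.

    ``pos`` is 0-based on ``genome`` (a dict of strings or pyfaidx
    Fasta); the scored window is the model input length centered on the
    variant (variant at index floor(L/2)).
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        raise ValueError(f"{snp_id}: only ACGT single-nucleotide variants are scored")
    L = network.spec.input_length
    start = pos - L // 2
    if start < 0 or start + L > len(genome[chrom]):
        raise ValueError(f"{snp_id}: window around {chrom}:{pos} leaves the chromosome")
    window = str(genome[chrom][start : start + L]).upper()
    center = pos - start
    if window[center] != ref:
        raise ValueError(
            f"{snp_id}: reference allele {ref} disagrees with genome base "
            f"{window[center]} at {chrom}:{pos}"
        )
    x_ref = one_hot_encode(window)
    x_alt = x_ref.copy()
    x_alt[:, center] = 0.0
    x_alt[BASE_INDEX[alt], center] = 1.0
    preds = network.predict(np.stack([x_ref, x_alt]))
    return SADProfile(snp_id, ref, alt, preds[1] - preds[0])


def score_vcf(network, genome, vcf_path):
    """SAD profiles for every SNV in a VCF; returns (profiles, n_skipped).

    Multi-allelic records yield one profile per alternative allele;
    indels and non-ACGT alleles are skipped with a logged reason.
    """
    import pysam

    profiles, skipped = [], 0
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt.upper() not in BASES:
                    logger.info("skipping %s: not a single-nucleotide variant",
                                rec.id or f"{rec.chrom}:{rec.pos}")
                    skipped += 1
                    continue
                snp_id = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}"
                profiles.append(
                    sad_profile(network, genome, rec.chrom, rec.pos - 1,
                                rec.ref, alt, snp_id)
                )
    return profiles, skipped


def rank_variants(profiles, threshold=0.1) -> pd.DataFrame:
    """Order SAD profiles by descending max |per-cell SAD|; flag those whose
    |profile mean| exceeds ``threshold`` (default 0.1)."""
    if not profiles:
        raise ValueError("no profiles to rank")
    rows = []
    for p in profiles:
        rows.append({
            "snp_id": p.snp_id,
            "ref": p.ref_allele,
            "alt": p.alt_allele,
            "max_abs_sad": p.max_abs_sad,
            "sad_mean": p.sad_mean,
            "flagged": abs(p.sad_mean) > threshold,
        })
    df = pd.DataFrame(rows).sort_values("max_abs_sad", ascending=False)
    return df.reset_index(drop=True)


def sad_table(profiles, cell_names=None) -> pd.DataFrame:
    """Per-SNP SAD table: one column per cell plus the profile mean."""
    T = len(profiles[0].per_cell_sad) if profiles else 0
    names = list(cell_names) if cell_names is not None else [f"cell_{t}" for t in range(T)]
    rows = []
    for p in profiles:
        row = {"snp_id": p.snp_id, "ref": p.ref_allele, "alt": p.alt_allele}
        row.update({f"sad_{n}": v for n, v in zip(names, p.per_cell_sad)})
        row["sad_mean"] = p.sad_mean
        rows.append(row)
    return pd.DataFrame(rows)
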