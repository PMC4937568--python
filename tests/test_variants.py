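import numpy as np
import pytest

from peaknet.sequence import BASES, one_hot_encode
from peaknet.variants import (rank_variants, sad_profile, sad_table,
                              saturation_mutagenesis, score_vcf, SADProfile)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# saturation mutagenesis


def test_constant_model_all_zero_scores(indicator_network, rng):
    net = indicator_network
    net.final.W[...] = 0.0
    net.final.b[...] = 0.0
    res = saturation_mutagenesis(net, _random_seq(rng, 60))
    np.testing.assert_allclose(res.delta, 0.0, atol=1e-12)
    np.testing.assert_allclose(res.loss_scores, 0.0, atol=1e-12)
    np.testing.assert_allclose(res.gain_scores, 0.0, atol=1e-12)


def test_reference_entries_zero_and_order_statistic(trained_tiny, rng):
    net, _, split, ds = trained_tiny
    seq = ds.sequences[int(split.test_idx[0])]
    res = saturation_mutagenesis(net, seq)
    L = len(seq)
    np.testing.assert_array_equal(
        res.delta[np.arange(L), res.ref_indices, :], 0.0)
    # gain + loss = max - min >= 0 everywhere
    assert np.all(res.gain_scores + res.loss_scores >= -1e-12)
    delta_c, loss_c, gain_c, ref_p = res.for_cell(0)
    assert delta_c.shape == (L, 4) and 0 < ref_p < 1


def test_satmut_rejects_wrong_length(trained_tiny):
    net, *_ = trained_tiny
    with pytest.raises(ValueError):
        saturation_mutagenesis(net, "ACGT" * 10)


def test_satmut_localizes_to_planted_footprint(trained_tiny):
    """Loss scores concentrate on planted motif positions."""
    net, _, split, ds = trained_tiny
    ratios = []
    picked = 0
    for i in map(int, split.test_idx):
        plants = [p for p in ds.plants[i] if p.motif_id == 0]
        if not plants or ds.activity[i, 0] == 0:
            continue
        res = saturation_mutagenesis(net, ds.sequences[i])
        loss = res.loss_scores[:, 0]
        mask = ds.footprint_mask(i)
        ratios.append(loss[mask].mean() / max(loss[~mask].mean(), 1e-9))
        picked += 1
        if picked == 10:
            break
    assert picked > 0
    assert np.median(ratios) > 3.0


# ---------------------------------------------------------------------------
# SAD profiles


def test_sad_zero_for_identical_alleles(trained_tiny):
    net, *_ = trained_tiny
    genome = {"c": "ACGT" * 50}
    prof = sad_profile(net, genome, "c", 100, "A", "A")
    np.testing.assert_array_equal(prof.per_cell_sad, 0.0)


def test_sad_antisymmetry(trained_tiny, rng):
    net, *_ = trained_tiny
    seq = _random_seq(rng, 200)
    pos = 100
    ref = seq[pos]
    alt = next(b for b in "ACGT" if b != ref)
    g_ref = {"c": seq}
    g_alt = {"c": seq[:pos] + alt + seq[pos + 1 :]}
    fwd = sad_profile(net, g_ref, "c", pos, ref, alt)
    rev = sad_profile(net, g_alt, "c", pos, alt, ref)
    np.testing.assert_array_equal(fwd.per_cell_sad, -rev.per_cell_sad)


def test_satmut_reproduces_sad_at_snp_position(trained_tiny, rng):
    net, *_ = trained_tiny
    seq = _random_seq(rng, 100)  # window == genome == model input
    pos = 50
    ref = seq[pos]
    alt = next(b for b in "ACGT" if b != ref)
    prof = sad_profile(net, {"c": seq}, "c", pos, ref, alt)
    res = saturation_mutagenesis(net, seq)
    np.testing.assert_allclose(prof.per_cell_sad,
                               res.delta[pos, BASES.index(alt), :], atol=1e-7)


def test_sad_ref_mismatch_names_position(trained_tiny):
    net, *_ = trained_tiny
    genome = {"c": "A" * 200}
    with pytest.raises(ValueError, match="c:100"):
        sad_profile(net, genome, "c", 100, "G", "T")


def test_sad_rejects_indel_alleles(trained_tiny):
    net, *_ = trained_tiny
    with pytest.raises(ValueError, match="single-nucleotide"):
        sad_profile(net, {"c": "A" * 200}, "c", 100, "AT", "A")


def test_sad_window_bounds_checked(trained_tiny):
    net, *_ = trained_tiny
    with pytest.raises(ValueError, match="leaves the chromosome"):
        sad_profile(net, {"c": "A" * 120}, "c", 10, "A", "C")


# ---------------------------------------------------------------------------
# VCF scoring


def _write_vcf(path, rows, contig="c", length=400):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos1, vid, ref, alt in rows:
            fh.write(f"{contig}\t{pos1}\t{vid}\t{ref}\t{alt}\t.\t.\t.\n")


def test_score_vcf_snvs_indels_multiallelic(tmp_path, trained_tiny, rng):
    net, *_ = trained_tiny
    seq = _random_seq(rng, 400)
    genome = {"c": seq}
    pos0 = 200
    ref = seq[pos0]
    alts = [b for b in "ACGT" if b != ref]
    _write_vcf(tmp_path / "v.vcf", [
        (pos0 + 1, "snv", ref, alts[0]),
        (pos0 + 1, "multi", ref, f"{alts[1]},{alts[2]}"),
        (151, "indel", seq[150] + seq[151], seq[150]),
    ])
    profiles, skipped = score_vcf(net, genome, str(tmp_path / "v.vcf"))
    assert skipped == 1
    assert [p.snp_id for p in profiles] == ["snv", "multi", "multi"]
    assert all(len(p.per_cell_sad) == 2 for p in profiles)


def test_sad_discriminates_causal_from_bystander(trained_tiny):
    """|SAD mean| separates motif-ablating SNPs from background SNPs."""
    from peaknet.metrics import auc
    from peaknet.synth import generate_variant_set

    net, _, split, ds = trained_tiny
    variants = generate_variant_set(ds, n_causal=40, n_bystander=40, seed=6)
    genome = {"g": ds.genome()}
    scores, labels = [], []
    for v in variants:
        pos = ds.site_offset(v.site) + v.pos
        prof = sad_profile(net, genome, "g", pos, v.ref, v.alt, v.snp_id)
        scores.append(abs(prof.sad_mean))
        labels.append(int(v.causal))
    assert auc(labels, scores) > 0.85


# ---------------------------------------------------------------------------
# ranking


def test_rank_variants_flags_and_orders():
    zeros = [SADProfile(f"z{i}", "A", "C", np.zeros(3)) for i in range(3)]
    hot = SADProfile("hot", "A", "C", np.array([0.25, 0.2, 0.15]))
    df = rank_variants(zeros + [hot], threshold=0.1)
    assert df.iloc[0]["snp_id"] == "hot"
    assert df["flagged"].sum() == 1
    assert bool(df.iloc[0]["flagged"])
    df2 = rank_variants(zeros, threshold=0.1)
    assert df2["flagged"].sum() == 0


def test_rank_variants_rejects_empty():
    with pytest.raises(ValueError):
        rank_variants([])


def test_sad_table_columns():
    profs = [SADProfile("s", "A", "C", np.array([0.1, -0.3]))]
    df = sad_table(profs, cell_names=["x", "y"])
    assert list(df.columns) == ["snp_id", "ref", "alt", "sad_x", "sad_y",
                                "sad_mean"]
    assert df.loc[0, "sad_mean"] == pytest.approx(-0.1)


# ---------------------------------------------------------------------------
# plotting


def test_satmut_plot_written(tmp_path, trained_tiny):
    from peaknet.plotting import plot_saturation_mutagenesis

    net, _, split, ds = trained_tiny
    res = saturation_mutagenesis(net, ds.sequences[0])
    out = tmp_path / "map.png"
    plot_saturation_mutagenesis(res, 0, cell_name="cell_0", path=str(out))
    assert out.stat().st_size > 0
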