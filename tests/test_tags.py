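"""Boundary extraction, UMI deduplication and chimera-rate estimation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tifseq2.tags import (dedup_umis, estimate_chimera_rate,
                          estimate_duplicate_rate, extract_boundary_pairs,
                          hamming)


def raw_row(**kw):
    base = dict(chrom="chr1", strand="+", mate5_start=1000, mate5_end=1075,
                mate3_start=5950, mate3_end=6025, umi="ACGTACGT", sample="s1")
    base.update(kw)
    return base


def tag_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "strand", "tss_pos", "pas_pos",
                                       "umi", "sample", "count"])


def tag(tss, pas, umi, count=1, chrom="chr1", strand="+", sample="s1"):
    return dict(chrom=chrom, strand=strand, tss_pos=tss, pas_pos=pas,
                umi=umi, sample=sample, count=count)


class TestExtractBoundaryPairs:
    def test_plus_strand_boundaries(self):
        tags, rejected = extract_boundary_pairs(pd.DataFrame([raw_row()]))
        assert rejected.empty
        assert tags.iloc[0]["tss_pos"] == 1000
        assert tags.iloc[0]["pas_pos"] == 6024

    def test_minus_strand_mirrors(self):
        tags, _ = extract_boundary_pairs(pd.DataFrame([raw_row(
            strand="-", strand3="-", mate5_start=5950, mate5_end=6025,
            mate3_start=1000, mate3_end=1075)]))
        assert tags.iloc[0]["tss_pos"] == 6024
        assert tags.iloc[0]["pas_pos"] == 1000

    def test_cross_chromosome_rejected(self):
        tags, rejected = extract_boundary_pairs(
            pd.DataFrame([raw_row(chrom3="chr2")]))
        assert tags.empty
        assert rejected.iloc[0]["reason"] == "cross_chromosome"

    def test_discordant_strand_rejected(self):
        _, rejected = extract_boundary_pairs(
            pd.DataFrame([raw_row(strand3="-")]))
        assert rejected.iloc[0]["reason"] == "discordant_strand"

    def test_improper_orientation_rejected(self):
        # 3' mate upstream of the 5' mate on the plus strand
        _, rejected = extract_boundary_pairs(pd.DataFrame([raw_row(
            mate3_start=100, mate3_end=175)]))
        assert rejected.iloc[0]["reason"] == "improper_orientation"


def brute_force_dedup(tags: pd.DataFrame, umi_mismatch=1, tss_shift=1,
                      method="directional"):
    """Independent O(n^2) connected-components oracle over unique tags."""
    unique = (tags.groupby(["sample", "chrom", "strand", "tss_pos", "pas_pos",
                            "umi"], as_index=False)["count"].sum())
    recs = unique.to_dict("records")
    g = nx.Graph()
    g.add_nodes_from(range(len(recs)))
    for i, j in itertools.combinations(range(len(recs)), 2):
        a, b = recs[i], recs[j]
        if (a["sample"], a["chrom"], a["strand"], a["pas_pos"]) != \
                (b["sample"], b["chrom"], b["strand"], b["pas_pos"]):
            continue
        if abs(a["tss_pos"] - b["tss_pos"]) > tss_shift:
            continue
        if hamming(a["umi"], b["umi"]) > umi_mismatch:
            continue
        if method == "directional":
            hi, lo = max(a["count"], b["count"]), min(a["count"], b["count"])
            if hi < 2 * lo - 1:
                continue
        g.add_edge(i, j)
    rows = []
    for comp in nx.connected_components(g):
        members = [recs[i] for i in comp]
        rep = min(members, key=lambda m: (-m["count"], m["tss_pos"],
                                          m["pas_pos"], m["umi"]))
        rows.append({**{k: rep[k] for k in ("chrom", "strand", "tss_pos",
                                            "pas_pos", "umi", "sample")},
                     "count": sum(m["count"] for m in members)})
    out = pd.DataFrame(rows, columns=["chrom", "strand", "tss_pos", "pas_pos",
                                      "umi", "sample", "count"])
    return out.sort_values(["chrom", "strand", "tss_pos", "pas_pos", "umi",
                            "sample"], kind="mergesort").reset_index(drop=True)


def random_tags(rng, n, umi_len=4, pos_span=15):
    umis = ["".join(rng.choice(list("ACGT"), umi_len)) for _ in range(n)]
    return tag_frame([
        tag(int(rng.integers(100, 100 + pos_span)),
            int(rng.integers(500, 503)), u) for u in umis])


class TestDedup:
    def test_identical_tags_collapse(self):
        out = dedup_umis(tag_frame([tag(100, 500, "ACGT"), tag(100, 500, "ACGT")]))
        assert len(out) == 1 and out.iloc[0]["count"] == 2

    def test_one_bp_tss_shift_merges(self):
        out = dedup_umis(tag_frame([tag(100, 500, "ACGT"), tag(101, 500, "ACGT")]))
        assert len(out) == 1

    def test_two_bp_tss_shift_does_not_merge(self):
        inp = tag_frame([tag(100, 500, "ACGT"), tag(102, 500, "ACGT")])
        out = dedup_umis(inp)
        assert len(out) == 2
        pd.testing.assert_frame_equal(out, brute_force_dedup(inp))

    def test_directional_count_rule_merges_error_umi(self):
        inp = tag_frame([tag(100, 500, "ACGTACGT", count=10),
                         tag(100, 500, "ACGTACGA", count=1)])
        out = dedup_umis(inp)
        assert len(out) == 1
        assert out.iloc[0]["count"] == 11
        assert out.iloc[0]["umi"] == "ACGTACGT"  # highest-count representative

    def test_equal_high_counts_stay_separate_under_directional(self):
        inp = tag_frame([tag(100, 500, "AAAA", count=5),
                         tag(100, 500, "AAAT", count=5)])
        assert len(dedup_umis(inp)) == 2
        assert len(dedup_umis(inp, method="cluster")) == 1

    def test_pas_position_is_held_exact(self):
        inp = tag_frame([tag(100, 500, "ACGT"), tag(100, 501, "ACGT")])
        assert len(dedup_umis(inp)) == 2
        assert len(dedup_umis(inp, pas_shift=1)) == 1

    def test_mixed_umi_lengths_error(self):
        inp = tag_frame([tag(100, 500, "ACGT"), tag(100, 500, "ACGTA")])
        with pytest.raises(ValueError, match="UMI"):
            dedup_umis(inp)

    def test_count_conservation_and_idempotence(self):
        rng = np.random.default_rng(5)
        inp = random_tags(rng, 300)
        out = dedup_umis(inp)
        assert out["count"].sum() == len(inp)
        again = dedup_umis(out)
        pd.testing.assert_frame_equal(again, out)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        inp = random_tags(rng, 200)
        shuffled = inp.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(dedup_umis(inp), dedup_umis(shuffled))

    @pytest.mark.parametrize("method", ["directional", "cluster"])
    def test_matches_brute_force_oracle(self, method):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            inp = random_tags(rng, 200)
            got = dedup_umis(inp, method=method)
            want = brute_force_dedup(inp, method=method)
            pd.testing.assert_frame_equal(got, want)


class TestChimeraEstimate:
    def test_zero_cross_barcode(self):
        est = estimate_chimera_rate(["s1"] * 10, ["s1"] * 10, k_samples=4)
        assert est.observed_fraction == 0.0 and est.corrected_rate == 0.0

    def test_closed_form_k4(self):
        s5 = ["s1"] * 1000
        s3 = ["s2"] * 30 + ["s1"] * 970
        est = estimate_chimera_rate(s5, s3, k_samples=4)
        assert est.observed_fraction == pytest.approx(0.03)
        assert est.corrected_rate == pytest.approx(0.04)

    def test_closed_form_k2(self):
        s5 = ["s1"] * 100
        s3 = ["s2"] * 5 + ["s1"] * 95
        est = estimate_chimera_rate(s5, s3, k_samples=2)
        assert est.corrected_rate == pytest.approx(0.10)

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_chimera_rate(["s1"] * 10, ["s1"] * 10, k_samples=1)

    def test_correction_capped_at_one(self):
        est = estimate_chimera_rate(["s1", "s1"], ["s2", "s3"], k_samples=2)
        assert est.corrected_rate == 1.0


class TestRateRecovery:
    def test_chimera_and_duplicate_rates_recovered_across_seeds(self):
        """Simulated libraries recover the configured chimera and PCR
        duplicate rates within 3 binomial standard errors."""
        from tifseq2.simulate import SimConfig, generate_reference, simulate_library

        for seed in range(1, 11):
            cfg = SimConfig(seed=seed)
            _, _, truth = generate_reference(cfg)
            pairs, truth = simulate_library(truth, cfg)
            n_mol = len(truth.molecules)

            est = estimate_chimera_rate(pairs["sample"], pairs["sample3"],
                                        cfg.n_samples)
            expected_cross = cfg.chimera_rate * (cfg.n_samples - 1) / cfg.n_samples
            se = np.sqrt(expected_cross * (1 - expected_cross) / len(pairs))
            assert abs(est.observed_fraction - expected_cross) <= 3 * se
            assert abs(est.corrected_rate - cfg.chimera_rate) <= \
                3 * se * cfg.n_samples / (cfg.n_samples - 1)

            dup = estimate_duplicate_rate(pairs)
            se_dup = np.sqrt(cfg.pcr_dup_rate * (1 - cfg.pcr_dup_rate) / n_mol)
            assert abs(dup - cfg.pcr_dup_rate) <= 3 * se_dup
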