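import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabomr import SimConfig, clump, harmonize, instrument_strength, \
    ld_r2, qc_filter, simulate_ld_panel
from metabomr.io_formats import ValidationError

from conftest import make_record


class TestQcFilter:
    def test_strand_ambiguous_removed(self):
        kept, log = qc_filter([make_record(ea="A", oa="T"),
                               make_record(snp_id="rs2", pos=2)])
        assert [r.snp_id for r in kept] == ["rs2"]
        assert log["palindromic"] == 1

    @pytest.mark.parametrize("info,kept_expected", [(0.89, 0), (0.90, 1), (0.95, 1)])
    def test_info_boundary_inclusive_keep(self, info, kept_expected):
        kept, _ = qc_filter([make_record(info=info)])
        assert len(kept) == kept_expected

    def test_duplicated_rsid_drops_both(self):
        records = [make_record(pos=1), make_record(pos=2),
                   make_record(snp_id="rs9", pos=3)]
        kept, log = qc_filter(records)
        assert [r.snp_id for r in kept] == ["rs9"]
        assert log["duplicate_rsid"] == 2

    def test_duplicated_position_drops_both(self):
        records = [make_record(snp_id="rs1", pos=5),
                   make_record(snp_id="rs2", pos=5),
                   make_record(snp_id="rs3", pos=6)]
        kept, log = qc_filter(records)
        assert [r.snp_id for r in kept] == ["rs3"]
        assert log["duplicate_position"] == 2

    @pytest.mark.parametrize("chrom", ["X", "Y"])
    def test_sex_chromosomes_removed(self, chrom):
        kept, log = qc_filter([make_record(chrom=chrom)])
        assert not kept and log["sex_chromosome"] == 1

    def test_missing_rsid_removed(self):
        kept, log = qc_filter([make_record(snp_id="1:100_A_G")])
        assert not kept and log["missing_rsid"] == 1

    def test_bookkeeping_kept_plus_rejected(self):
        records = [make_record(snp_id=f"rs{i}", pos=i,
                               ea="A", oa="T" if i % 3 == 0 else "G",
                               info=0.5 if i % 4 == 0 else 1.0)
                   for i in range(1, 30)]
        kept, log = qc_filter(records)
        assert len(kept) + sum(log.values()) == len(records)


class TestLdR2:
    def test_self_correlation_is_one(self):
        d = np.array([[0.0, 0.0], [1, 1], [2, 2], [0, 0]])
        assert ld_r2(d, ["a", "b"], "a", "b") == pytest.approx(1.0)

    def test_anticorrelation_squares_to_one(self):
        d = np.column_stack([[0, 1, 2, 0], [2, 1, 0, 2]]).astype(float)
        assert ld_r2(d, ["a", "b"], "a", "b") == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        d = np.column_stack([[0, 0, 1, 1], [0, 1, 0, 1]]).astype(float)
        assert ld_r2(d, ["a", "b"], "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_errors(self):
        d = np.column_stack([[1, 1, 1], [0, 1, 2]]).astype(float)
        with pytest.raises(ValidationError, match="variance"):
            ld_r2(d, ["a", "b"], "a", "b")


def brute_force_clump(records, dosages, snp_ids, p_thresh, r2_thresh, window_kb):
    """Independent greedy oracle using raw numpy correlations."""
    idx = {s: i for i, s in enumerate(snp_ids)}
    pool = sorted((r for r in records if r.pval < p_thresh),
                  key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id))
    out = []
    while pool:
        head, pool = pool[0], pool[1:]
        out.append(head.snp_id)
        keep = []
        for r in pool:
            remove = False
            if (r.chrom == head.chrom
                    and abs(r.pos - head.pos) <= window_kb * 1000
                    and r.snp_id in idx and head.snp_id in idx):
                a, b = dosages[:, idx[head.snp_id]], dosages[:, idx[r.snp_id]]
                if a.std() > 0 and b.std() > 0:
                    remove = np.corrcoef(a, b)[0, 1] ** 2 > r2_thresh
            if not remove:
                keep.append(r)
        pool = keep
    return out


class TestClump:
    def _two_snp(self, r):
        """Panel of two SNPs with dosage correlation ~r via shared draws."""
        rng = np.random.default_rng(0)
        n = 2000
        base = rng.integers(0, 3, n).astype(float)
        other = np.where(rng.random(n) < r, base, rng.integers(0, 3, n))
        return np.column_stack([base, other]), ["rs1", "rs2"]

    def test_linked_pair_collapses_to_smallest_p(self):
        dosages, ids = self._two_snp(0.9)
        records = [make_record(snp_id="rs1", pos=100, pval=1e-8),
                   make_record(snp_id="rs2", pos=10_100, pval=1e-6)]
        index, _ = clump(records, dosages, ids, r2_thresh=0.1)
        assert index == ["rs1"]

    def test_unlinked_pair_retained(self):
        dosages, ids = self._two_snp(0.0)
        records = [make_record(snp_id="rs1", pos=100, pval=1e-8),
                   make_record(snp_id="rs2", pos=10_100, pval=1e-6)]
        index, _ = clump(records, dosages, ids, r2_thresh=0.1)
        assert index == ["rs1", "rs2"]

    def test_p_threshold_filters_everything(self):
        records = [make_record(snp_id="rs1", pval=1e-4),
                   make_record(snp_id="rs2", pos=200, pval=1e-3)]
        index, log = clump(records, None, None, p_thresh=1e-5)
        assert index == [] and log["n_candidates"] == 0

    def test_snp_absent_from_panel_kept_and_logged(self):
        dosages, ids = self._two_snp(0.9)
        records = [make_record(snp_id="rs1", pos=100, pval=1e-8),
                   make_record(snp_id="rs99", pos=200, pval=1e-6)]
        index, log = clump(records, dosages, ids)
        assert index == ["rs1", "rs99"]
        assert log["missing_from_panel"] == ["rs99"]

    def test_returned_indices_mutually_unlinked(self):
        cfg = SimConfig(seed=21, n_snps=15, n_samples_panel=800,
                        ld_blocks=((5, 0.8), (5, 0.6)))
        ids, dosages = simulate_ld_panel(cfg)
        rng = np.random.default_rng(5)
        records = [make_record(snp_id=ids[j], pos=1 + j * 1000,
                               pval=float(rng.uniform(1e-10, 1e-6)))
                   for j in range(15)]
        index, _ = clump(records, dosages, ids, r2_thresh=0.1, window_kb=500)
        for i, a in enumerate(index):
            for b in index[i + 1:]:
                assert ld_r2(dosages, ids, a, b) <= 0.1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        """Greedy clumping equals an independent oracle on random <=20-SNP
        instances with random LD blocks, p-values and positions."""
        rng = np.random.default_rng(seed)
        n_snps = int(rng.integers(2, 20))
        b1 = int(rng.integers(1, n_snps + 1))
        cfg = SimConfig(seed=seed, n_snps=n_snps, n_samples_panel=300,
                        ld_blocks=((b1, float(rng.uniform(0, 0.95))),))
        ids, dosages = simulate_ld_panel(cfg)
        records = [make_record(snp_id=ids[j], chrom=str(1 + j % 2),
                               pos=int(rng.integers(1, 2_000_000)),
                               pval=float(rng.uniform(1e-12, 1e-4)))
                   for j in range(n_snps)]
        kwargs = dict(p_thresh=1e-5, r2_thresh=0.1, window_kb=500)
        expected = brute_force_clump(records, dosages, ids, **kwargs)
        actual, _ = clump(records, dosages, ids, **kwargs)
        assert actual == expected


class TestHarmonize:
    def test_aligned_pair_untouched(self):
        ex = [make_record(beta=0.1)]
        oc = [make_record(beta=-0.05, se=0.01)]
        panel, _ = harmonize(ex, oc)
        assert panel.big_gamma[0] == pytest.approx(-0.05)
        assert not panel.flipped[0]

    def test_swapped_alleles_flip_sign(self):
        ex = [make_record(ea="A", oa="G", beta=0.1)]
        oc = [make_record(ea="G", oa="A", beta=-0.05)]
        panel, _ = harmonize(ex, oc)
        assert panel.big_gamma[0] == pytest.approx(0.05)
        assert panel.flipped[0]

    def test_allele_mismatch_dropped_with_log(self):
        ex = [make_record(ea="A", oa="G"), make_record(snp_id="rs2", pos=2)]
        oc = [make_record(ea="A", oa="C"), make_record(snp_id="rs2", pos=2)]
        panel, log = harmonize(ex, oc)
        assert panel.snp_ids == ("rs2",)
        assert ("rs1", "allele mismatch") in log["dropped"]

    def test_double_flip_round_trips(self):
        ex = [make_record(beta=0.1), make_record(snp_id="rs2", pos=2, beta=-0.2)]
        oc = [make_record(ea="G", oa="A", beta=-0.05),
              make_record(snp_id="rs2", pos=2, beta=0.07)]
        once, _ = harmonize(ex, oc)
        oc_flipped_back = [r.flipped() if f else r
                           for r, f in zip(oc, once.flipped)]
        twice, _ = harmonize(ex, oc_flipped_back)
        np.testing.assert_allclose(once.big_gamma, twice.big_gamma)
        assert not twice.flipped.any()  # already aligned: idempotent

    def test_empty_intersection_errors(self):
        with pytest.raises(ValidationError, match="no SNPs shared"):
            harmonize([make_record(snp_id="rs1")], [make_record(snp_id="rs2", pos=2)])


class TestInstrumentStrength:
    def test_f_statistic_and_pve_formulas(self):
        records = [make_record(beta=0.1, se=0.02)]
        rep = instrument_strength(records, n=7824)
        assert rep.f_stat[0] == pytest.approx(25.0)
        assert rep.pve[0] == pytest.approx(0.01 / (0.01 + 7824 * 0.0004), rel=1e-6)
        assert rep.pve[0] == pytest.approx(0.003185, abs=5e-6)

    def test_null_instrument(self):
        rep = instrument_strength([make_record(beta=0.0, pval=0.9)], n=1000)
        assert rep.f_stat[0] == 0.0 and rep.pve[0] == 0.0

    def test_totals(self):
        records = [make_record(snp_id=f"rs{i}", pos=i, beta=0.1, se=0.02)
                   for i in range(1, 4)]
        rep = instrument_strength(records, n=1000)
        assert rep.mean_f == pytest.approx(25.0)
        assert rep.total_pve == pytest.approx(3 * rep.pve[0])

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            instrument_strength([make_record()], n=2)
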