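import pytest

from mrsuite.instruments import (
    EmptyInstrumentError,
    filter_strong,
    harmonize,
    instrument_diagnostics,
    rescore_instruments,
    select_instruments,
)
from mrsuite.summary_io import GwasTable

from conftest import make_record


def table(records, name="exposure"):
    return GwasTable(records=records, trait_name=name)


class TestSelectInstruments:
    def test_singleton(self):
        t = table([make_record("rs1", pval=1e-9)])
        sel = select_instruments(t)
        assert [s.snp_id for s in sel.snps] == ["rs1"]

    def test_greedy_by_p_within_window(self):
        # greedy rule by hand: p-order is pos3e6 (1e-12), pos1e6 (1e-10),
        # pos1.5e6 (1e-9); the middle SNP is within 1 Mb of pos 1e6 -> dropped
        t = table([
            make_record("a", "1", 1_000_000, pval=1e-10),
            make_record("b", "1", 1_500_000, pval=1e-9),
            make_record("c", "1", 3_000_000, pval=1e-12),
        ])
        sel = select_instruments(t)
        assert {s.pos for s in sel.snps} == {1_000_000, 3_000_000}

    def test_exhaustive_p_minimality_on_small_instances(self, rng):
        # the greedy pick always contains the globally smallest p-value and
        # every retained pair respects the window
        for _ in range(20):
            n = rng.integers(3, 8)
            recs = [
                make_record(f"rs{i}", "1", int(rng.integers(1, 6) * 600_000),
                            pval=float(rng.uniform(1e-12, 1e-8)))
                for i in range(n)
            ]
            recs = [r for i, r in enumerate(recs)
                    if r.pos not in {x.pos for x in recs[:i]}]
            sel = select_instruments(table(recs), window_bp=1_000_000)
            best = min(recs, key=lambda r: r.pval)
            assert best.snp_id in {s.snp_id for s in sel.snps}
            pos = sorted(s.pos for s in sel.snps)
            assert all(b - a >= 1_000_000 for a, b in zip(pos, pos[1:]))

    def test_row_order_invariance(self, rng):
        recs = [
            make_record(f"rs{i}", str(i % 2 + 1), int(1e6 + i * 4e5),
                        pval=float(rng.uniform(1e-12, 1e-8)))
            for i in range(12)
        ]
        sel1 = select_instruments(table(list(recs)))
        shuffled = list(recs)
        rng.shuffle(shuffled)
        sel2 = select_instruments(table(shuffled))
        assert [s.snp_id for s in sel1.snps] == [s.snp_id for s in sel2.snps]

    def test_no_significant_snp_errors(self):
        with pytest.raises(EmptyInstrumentError):
            select_instruments(table([make_record(pval=1e-3)]))


def _pair(sel, data, snp_id):
    return next(p for p in data.pairs if p.snp_id == snp_id)


class TestHarmonize:
    def exposure_set(self):
        return select_instruments(table([
            make_record("rs1", "1", 1_000_000, "A", "G", 0.3, 0.1, 0.02, 1e-10),
            make_record("rs2", "2", 1_000_000, "C", "T", 0.2, 0.08, 0.02, 1e-9),
        ]))

    def test_identical_alleles_copied(self):
        sel = self.exposure_set()
        out = table([make_record("rs1", "1", 1_000_000, "A", "G", 0.31, 0.2, 0.05, 0.1)],
                    "outcome")
        data = harmonize(sel, out)
        p = _pair(sel, data, "rs1")
        assert p.beta_out == 0.2 and not p.flipped_flag
        assert data.n_missing == 1  # rs2 absent

    def test_swapped_alleles_flip_sign_and_frequency(self):
        sel = self.exposure_set()
        out = table([make_record("rs1", "1", 1_000_000, "G", "A", 0.3, 0.2, 0.05, 0.1)],
                    "outcome")
        p = _pair(sel, harmonize(sel, out), "rs1")
        assert p.beta_out == -0.2 and p.eaf_out == 0.7 and p.flipped_flag

    def test_strand_complement_resolved(self):
        # exposure A/G; outcome reports T/C (same variant, other strand)
        sel = self.exposure_set()
        out = table([make_record("rs1", "1", 1_000_000, "T", "C", 0.3, 0.2, 0.05, 0.1)],
                    "outcome")
        p = _pair(sel, harmonize(sel, out), "rs1")
        assert p.beta_out == 0.2 and not p.flipped_flag

    def test_irreconcilable_alleles_dropped(self):
        sel = self.exposure_set()
        out = table([make_record("rs1", "1", 1_000_000, "A", "C", 0.3, 0.2, 0.05, 0.1)],
                    "outcome")
        data = harmonize(sel, out)
        assert data.n_irreconcilable == 1
        assert data.drop_reasons["rs1"] == "irreconcilable_alleles"

    def palindromic_set(self, eaf_exp):
        return select_instruments(table([
            make_record("rs1", "1", 1_000_000, "A", "T", eaf_exp, 0.1, 0.02, 1e-10),
        ]))

    def test_palindromic_ambiguous_dropped(self):
        sel = self.palindromic_set(eaf_exp=0.50)
        out = table([make_record("rs1", "1", 1_000_000, "A", "T", 0.5, 0.2, 0.05, 0.1)],
                    "outcome")
        data = harmonize(sel, out, palindromic_policy="drop_ambiguous")
        assert data.n_available == 0 and data.n_dropped_palindromic == 1

    def test_palindromic_inferred_by_frequency(self):
        sel = self.palindromic_set(eaf_exp=0.1)
        # outcome frequency on the opposite side of 0.5 -> orientation flip
        out = table([make_record("rs1", "1", 1_000_000, "A", "T", 0.9, 0.2, 0.05, 0.1)],
                    "outcome")
        p = _pair(sel, harmonize(sel, out), "rs1")
        assert p.flipped_flag and p.beta_out == -0.2
        # same side -> kept as-is
        out2 = table([make_record("rs1", "1", 1_000_000, "A", "T", 0.12, 0.2, 0.05, 0.1)],
                     "outcome")
        p2 = _pair(sel, harmonize(sel, out2), "rs1")
        assert not p2.flipped_flag and p2.beta_out == 0.2

    def test_palindromic_drop_all_policy(self):
        sel = self.palindromic_set(eaf_exp=0.1)
        out = table([make_record("rs1", "1", 1_000_000, "A", "T", 0.1, 0.2, 0.05, 0.1)],
                    "outcome")
        data = harmonize(sel, out, palindromic_policy="drop_all")
        assert data.n_available == 0 and data.n_dropped_palindromic == 1

    def test_harmonization_idempotent(self):
        # writing the harmonized outcome effects back as a table aligned on
        # the exposure alleles and re-harmonizing changes nothing
        sel = self.exposure_set()
        out = table([
            make_record("rs1", "1", 1_000_000, "G", "A", 0.3, 0.2, 0.05, 0.1),
            make_record("rs2", "2", 1_000_000, "C", "T", 0.25, -0.1, 0.04, 0.2),
        ], "outcome")
        data1 = harmonize(sel, out)
        realigned = table([
            make_record(p.snp_id, "1", 1_000_000,
                        sel.snps[i].effect_allele, sel.snps[i].other_allele,
                        p.eaf_out, p.beta_out, p.se_out, 0.1)
            for i, p in enumerate(data1.pairs)
        ], "outcome")
        data2 = harmonize(sel, realigned)
        for p1, p2 in zip(data1.pairs, data2.pairs):
            assert p2.beta_out == p1.beta_out and not p2.flipped_flag

    def test_allele_flip_equivariance(self):
        # negating an outcome record's beta while swapping its alleles must
        # give identical harmonized data
        sel = self.exposure_set()
        rec = make_record("rs1", "1", 1_000_000, "A", "G", 0.3, 0.2, 0.05, 0.1)
        flipped = make_record("rs1", "1", 1_000_000, "G", "A", 0.7, -0.2, 0.05, 0.1)
        d1 = harmonize(sel, table([rec], "o"))
        d2 = harmonize(sel, table([flipped], "o"))
        assert d1.pairs[0].beta_out == d2.pairs[0].beta_out
        assert d1.pairs[0].eaf_out == pytest.approx(d2.pairs[0].eaf_out)


class TestDiagnostics:
    def test_f_statistic_arithmetic(self):
        sel = select_instruments(table([
            make_record("rs1", "1", 1_000_000, beta=0.1, se=0.02, pval=1e-10),
            make_record("rs2", "2", 1_000_000, beta=0.0, se=0.05, pval=1e-9),
        ]))
        diag = instrument_diagnostics(sel, n_exposure=10_000)
        assert diag.f_stats[0] == pytest.approx(25.0)
        assert diag.f_stats[1] == 0.0

    def test_f_invariant_under_allele_flip(self):
        sel = select_instruments(table([
            make_record("rs1", "1", 1_000_000, "A", "G", 0.3, 0.1, 0.02, 1e-10)]))
        flipped = select_instruments(table([
            make_record("rs1", "1", 1_000_000, "G", "A", 0.7, -0.1, 0.02, 1e-10)]))
        d1 = instrument_diagnostics(sel, 10_000)
        d2 = instrument_diagnostics(flipped, 10_000)
        assert d1.f_stats[0] == d2.f_stats[0]

    def test_r2_forms(self):
        sel = select_instruments(table([
            make_record("rs1", "1", 1_000_000, eaf=0.5, beta=0.1, se=0.02, pval=1e-10)]))
        diag = instrument_diagnostics(sel, n_exposure=10_000)
        assert diag.r2_from_eaf == pytest.approx(2 * 0.5 * 0.5 * 0.01)
        f = 25.0
        assert diag.r2_from_f == pytest.approx(f / (f + 10_000 - 2))
        assert diag.r2_total == diag.r2_from_eaf

    def test_r2_falls_back_when_eaf_missing(self):
        sel = select_instruments(table([
            make_record("rs1", "1", 1_000_000, eaf=None, beta=0.1, se=0.02, pval=1e-10)]))
        diag = instrument_diagnostics(sel, n_exposure=10_000)
        assert diag.r2_from_eaf is None
        assert diag.r2_total == pytest.approx(diag.r2_from_f)


class TestFilterStrong:
    def test_threshold_keeps_strong_only(self):
        sel = select_instruments(table([
            make_record("rs1", "1", 1_000_000, beta=0.10, se=0.02, pval=1e-10),  # F=25
            make_record("rs2", "2", 1_000_000, beta=0.06, se=0.02, pval=1e-9),   # F=9
            make_record("rs3", "3", 1_000_000, beta=0.0663325, se=0.02, pval=1e-9),  # F=11
        ]))
        diag = instrument_diagnostics(sel, 10_000)
        kept = filter_strong(sel, diag, f_min=10)
        assert [s.snp_id for s in kept.snps] == ["rs1", "rs3"]

    def test_all_strong_is_identity(self):
        sel = select_instruments(table([
            make_record("rs1", "1", 1_000_000, beta=0.1, se=0.02, pval=1e-10),
            make_record("rs2", "2", 1_000_000, beta=0.2, se=0.02, pval=1e-9),
        ]))
        diag = instrument_diagnostics(sel, 10_000)
        kept = filter_strong(sel, diag)
        assert kept.snps == sel.snps

    def test_rescore_against_alternative_exposure(self):
        sel = select_instruments(table([
            make_record("rs1", "1", 1_000_000, "A", "G", 0.3, 0.1, 0.02, 1e-10),
            make_record("rs2", "2", 1_000_000, "C", "T", 0.2, 0.08, 0.02, 1e-9),
        ]))
        alt = table([
            make_record("rs1", "1", 1_000_000, "G", "A", 0.7, -0.05, 0.01, 1e-6)],
            "vb")
        rescored = rescore_instruments(sel, alt)
        assert len(rescored.snps) == 1
        # aligned back onto the instrument effect allele
        assert rescored.snps[0].beta == pytest.approx(0.05)
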