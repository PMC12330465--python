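import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoruler.constants import AVOGADRO, DNA_MASS_DIPLOID_HUMAN
from immunoruler.io_formats import PrecursorTable, ProteinRecord
from immunoruler.quantify import (
    PeptideIntensityMatrix,
    aggregate_precursors,
    b2m_pseudocounts,
    filter_by_pg_q_value,
    molar_mass,
    proteomic_ruler,
)
from tests.conftest import make_precursor_table


class TestMolarMass:
    @pytest.mark.parametrize(
        "seq,expected",
        [("G", 57.0519 + 18.0153), ("AG", 71.0788 + 57.0519 + 18.0153)],
    )
    def test_known_masses(self, seq, expected):
        assert molar_mass(seq) == pytest.approx(expected, abs=1e-9)

    def test_empty_and_nonstandard_error(self):
        with pytest.raises(ValueError):
            molar_mass("")
        with pytest.raises(ValueError, match="X"):
            molar_mass("AXA")


class TestQValueFilter:
    def _table(self, qs):
        rows = [
            (f"p{i}", "ALDKVEASL", "ALDKVEASL", 1, "PG", "G", q, 1.0)
            for i, q in enumerate(qs)
        ]
        return make_precursor_table(rows, ["s1"])

    def test_strict_threshold(self):
        table = self._table([0.005, 0.01, 0.02])
        kept = filter_by_pg_q_value(table, 0.01)
        assert list(kept.data["pg_q_value"]) == [0.005]

    def test_absent_q_dropped_with_warning(self):
        table = self._table([0.005, np.nan])
        with pytest.warns(UserWarning, match="1 precursors"):
            kept = filter_by_pg_q_value(table, 0.01)
        assert kept.n_rows == 1

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            filter_by_pg_q_value(self._table([0.005]), 0.0)


class TestAggregatePrecursors:
    def test_charge_variants_summed(self, tiny_precursors):
        mat = aggregate_precursors(tiny_precursors, key="stripped")
        assert mat.intensities.loc["ALDKVEASL", "s1"] == 150.0
        assert mat.intensities.loc["KTWGQYWQV", "s1"] == 7.5

    def test_all_missing_stays_missing(self, tiny_precursors):
        mat = aggregate_precursors(tiny_precursors, key="stripped")
        assert np.isnan(mat.intensities.loc["ALDKVEASL", "s2"])
        assert mat.intensities.loc["KTWGQYWQV", "s2"] == 30.0

    def test_brute_force_oracle(self):
        """Aggregation equals a per-cell loop over precursor rows."""
        rng = np.random.default_rng(42)
        samples = ["s1", "s2", "s3"]
        peptides = ["AAAK", "CCCR", "DDDY"]
        rows = []
        for i in range(10):
            pep = peptides[rng.integers(3)]
            vals = [
                rng.lognormal(5, 1) if rng.random() > 0.3 else np.nan
                for _ in samples
            ]
            rows.append((f"p{i}", pep, pep, int(rng.integers(1, 4)), "PG", "G", 0.001, *vals))
        table = make_precursor_table(rows, samples)
        mat = aggregate_precursors(table, key="stripped")
        for pep in sorted({r[1] for r in rows}):
            for j, s in enumerate(samples):
                contrib = [r[7 + j] for r in rows if r[1] == pep and np.isfinite(r[7 + j])]
                expected = sum(contrib) if contrib else np.nan
                got = mat.intensities.loc[pep, s]
                assert (np.isnan(got) and np.isnan(expected)) or got == pytest.approx(expected)


def _protein_matrix(data, samples):
    df = pd.DataFrame(data, columns=samples)
    df.index = pd.Index([f"P{i}" for i in range(len(df))], name="protein")
    return df


class TestProteomicRuler:
    def test_single_histone_arithmetic(self):
        """One protein that is the sole histone with M ~ 15 kDa."""
        seq = "G" * 262  # 262 glycines + water = 14966.02 g/mol
        M = molar_mass(seq)
        rec = ProteinRecord("P0", "H4C1", seq, is_histone=True)
        intens = PeptideIntensityMatrix(
            _protein_matrix([[1000.0]], ["s1"]).rename(index={"P0": "P0"}),
            level="protein_group",
        )
        copies = proteomic_ruler(intens, [rec])
        expected = DNA_MASS_DIPLOID_HUMAN * AVOGADRO / M
        assert copies.copies.loc["P0", "s1"] == pytest.approx(expected, rel=1e-12)

    def test_sample_scale_invariance(self, small_dataset):
        truth, immuno, proteome, result = small_dataset
        scaled = proteome.data.copy()
        scaled[proteome.samples[0]] *= 10.0
        res2 = proteomic_ruler(
            aggregate_precursors(PrecursorTable(scaled, proteome.samples), "protein_group"),
            truth.proteome.records,
        )
        base = proteomic_ruler(
            aggregate_precursors(proteome, "protein_group"), truth.proteome.records
        )
        pd.testing.assert_frame_equal(res2.copies, base.copies, rtol=1e-12)

    def test_missing_intensity_gives_missing_copies(self):
        recs = [
            ProteinRecord("P0", "H4C1", "G" * 100, True),
            ProteinRecord("P1", "GENE1", "A" * 100, False),
        ]
        mat = _protein_matrix([[100.0, 100.0], [np.nan, 50.0]], ["s1", "s2"])
        intens = PeptideIntensityMatrix(mat, level="protein_group")
        copies = proteomic_ruler(intens, recs)
        assert np.isnan(copies.copies.loc["P1", "s1"])
        assert np.isfinite(copies.copies.loc["P1", "s2"])

    def test_no_histone_signal_names_sample(self):
        recs = [
            ProteinRecord("P0", "H4C1", "G" * 100, True),
            ProteinRecord("P1", "GENE1", "A" * 100, False),
        ]
        mat = _protein_matrix([[100.0, np.nan], [1.0, 50.0]], ["s1", "s2"])
        intens = PeptideIntensityMatrix(mat, level="protein_group")
        with pytest.raises(ValueError, match="s2"):
            proteomic_ruler(intens, recs)

    def test_brute_force_oracle(self):
        """Ruler equals elementwise arithmetic recomputation on a random
        instance with several histones."""
        rng = np.random.default_rng(3)
        samples = ["s1", "s2"]
        recs = []
        n = 8
        for i in range(n):
            hist = i < 3
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=rng.integers(50, 200)))
            recs.append(ProteinRecord(f"P{i}", "H4C1" if hist else f"G{i}", seq, hist))
        mat = _protein_matrix(rng.lognormal(10, 1, size=(n, 2)), samples)
        copies = proteomic_ruler(PeptideIntensityMatrix(mat, level="protein_group"), recs)
        for j, s in enumerate(samples):
            hist_sum = sum(mat.iloc[i, j] for i in range(3))
            for i in range(n):
                expected = (
                    mat.iloc[i, j] / hist_sum * DNA_MASS_DIPLOID_HUMAN * AVOGADRO
                    / molar_mass(recs[i].sequence)
                )
                assert copies.copies.iloc[i, j] == pytest.approx(expected, rel=1e-12)


def _antigen_matrix(data, samples, genes=None):
    df = pd.DataFrame(data, columns=samples)
    df.index = pd.Index([f"PEP{i}" for i in range(len(df))], name="peptide")
    meta = pd.DataFrame(index=df.index)
    if genes:
        meta["gene"] = genes
    return PeptideIntensityMatrix(df, level="immunopeptide", feature_meta=meta)


def _copies_with_b2m(b2m_per_sample, samples):
    recs = [
        ProteinRecord("PH", "H4C1", "G" * 100, True),
        ProteinRecord("PB", "B2M", "A" * 119, False),
    ]
    mb = molar_mass("A" * 119)
    hist_intensity = 1000.0
    # choose B2M intensity so the ruler returns exactly the requested copies
    b2m_int = [
        c * mb * hist_intensity / (DNA_MASS_DIPLOID_HUMAN * AVOGADRO)
        for c in b2m_per_sample
    ]
    mat = pd.DataFrame(
        [[hist_intensity] * len(samples), b2m_int], columns=samples,
        index=pd.Index(["PH", "PB"], name="protein"),
    )
    intens = PeptideIntensityMatrix(mat, level="protein_group",
                                    feature_meta=pd.DataFrame({"gene": ["H4C1", "B2M"]},
                                                              index=mat.index))
    return proteomic_ruler(intens, recs)


class TestB2MPseudocounts:
    def test_two_antigen_worked_example(self):
        copies = _copies_with_b2m([1e5], ["s1"])
        antigens = _antigen_matrix([[75.0], [25.0]], ["s1"])
        ps = b2m_pseudocounts(antigens, copies)
        assert ps.pseudocounts.loc["PEP0", "s1"] == pytest.approx(7.5e4, rel=1e-9)
        assert ps.pseudocounts.loc["PEP1", "s1"] == pytest.approx(2.5e4, rel=1e-9)
        assert ps.pseudocounts["s1"].sum() == pytest.approx(1e5, rel=1e-12)

    def test_single_antigen_gets_all_b2m(self):
        copies = _copies_with_b2m([4.2e4], ["s1"])
        ps = b2m_pseudocounts(_antigen_matrix([[123.0]], ["s1"]), copies)
        assert ps.pseudocounts.iloc[0, 0] == pytest.approx(4.2e4, rel=1e-9)

    def test_antigen_scale_invariance(self):
        copies = _copies_with_b2m([1e5, 2e5], ["s1", "s2"])
        a1 = _antigen_matrix([[75.0, 10.0], [25.0, 40.0]], ["s1", "s2"])
        a2 = _antigen_matrix([[75.0 * 7, 10.0], [25.0 * 7, 40.0]], ["s1", "s2"])
        p1 = b2m_pseudocounts(a1, copies).pseudocounts
        p2 = b2m_pseudocounts(a2, copies).pseudocounts
        pd.testing.assert_frame_equal(p1, p2, rtol=1e-12)

    def test_missing_b2m_names_sample(self):
        copies = _copies_with_b2m([1e5, 1e5], ["s1", "s2"])
        copies.copies.loc["PB", "s2"] = np.nan
        with pytest.raises(ValueError, match="s2"):
            b2m_pseudocounts(_antigen_matrix([[1.0, 1.0]], ["s1", "s2"]), copies)

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(
            st.lists(st.floats(min_value=0.1, max_value=1e9), min_size=2, max_size=2),
            min_size=1,
            max_size=12,
        ),
        b2m=st.floats(min_value=1e2, max_value=1e7),
    )
    def test_conservation_property(self, data, b2m):
        """Per-sample pseudocount totals equal B2M copies for any input."""
        samples = ["s1", "s2"]
        copies = _copies_with_b2m([b2m, b2m], samples)
        ps = b2m_pseudocounts(_antigen_matrix(data, samples), copies)
        totals = ps.pseudocounts.sum(axis=0)
        assert np.allclose(totals, ps.b2m_copies, rtol=1e-9)
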