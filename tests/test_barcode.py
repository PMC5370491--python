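"""Barcode screen: divergence, masking, read mapping, the matrix M."""

import numpy as np
import pytest

from contamkit.barcode import (
    ContaminationMatrix,
    ReferencePanel,
    build_contamination_matrix,
    default_max_mismatch,
    diagnostic_mask,
    map_read,
    pairwise_divergence,
    screen_sample,
)
from contamkit.simulate import (
    ContaminationScenario,
    simulate_barcode_experiment,
)


def brute_force_map(read, panel, max_mismatch):
    """Oracle: enumerate every (reference, strand, offset) placement."""
    def revcomp(s):
        return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]

    hits = []
    for r, ref in enumerate(panel.sequences):
        for strand, query in (("+", read), ("-", revcomp(read))):
            for off in range(len(ref) - len(query) + 1):
                mm = sum(
                    1
                    for a, b in zip(query, ref[off : off + len(query)])
                    if a != b or a not in "ACGT"
                )
                if mm <= max_mismatch:
                    hits.append((r, strand, off, mm))
    if not hits:
        return None, []
    best = min(h[3] for h in hits)
    return best, [h for h in hits if h[3] == best]


def toy_panel():
    rng = np.random.default_rng(77)
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 120)) for _ in range(3)]
    return ReferencePanel(
        ids=["r1", "r2", "r3"],
        species=["spA", "spB", "spC"],
        components=["target"] * 3,
        sequences=seqs,
    )


class TestPanel:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ReferencePanel(ids=["a", "b"], species=["x", "y"],
                           components=["target"] * 2, sequences=["ACGT", "ACG"])

    def test_empty_species_rejected(self):
        with pytest.raises(ValueError):
            ReferencePanel(ids=["a"], species=[""], components=["target"],
                           sequences=["ACGT"])


class TestDivergence:
    def test_identical_sequences(self):
        p = ReferencePanel(ids=["a", "b"], species=["x", "y"],
                           components=["target"] * 2, sequences=["ACGTACGT", "ACGTACGT"])
        assert pairwise_divergence(p).get("x", "y") == 0.0

    def test_single_difference(self):
        s = "A" * 351
        s2 = "C" + "A" * 350
        p = ReferencePanel(ids=["a", "b"], species=["x", "y"],
                           components=["target"] * 2, sequences=[s, s2])
        assert pairwise_divergence(p).get("x", "y") == pytest.approx(1 / 351)

    def test_species_pair_uses_minimum(self):
        s = "A" * 100
        near = "C" * 2 + "A" * 98      # 2% from s
        far = "C" * 30 + "A" * 70      # 30% from s
        p = ReferencePanel(
            ids=["a", "b1", "b2"], species=["x", "y", "y"],
            components=["target"] * 3, sequences=[s, far, near],
        )
        assert pairwise_divergence(p).get("x", "y") == pytest.approx(0.02)

    def test_pairwise_deletion_and_reliability(self):
        s1 = "ACGT" * 25
        s2 = "N" * 60 + s1[60:]
        p = ReferencePanel(ids=["a", "b"], species=["x", "y"],
                           components=["target"] * 2, sequences=[s1, s2])
        t = pairwise_divergence(p)
        assert t.get("x", "y") == 0.0  # identical where comparable
        assert t.unreliable[0, 1]  # only 40% of positions comparable

    def test_symmetry(self):
        t = pairwise_divergence(toy_panel())
        assert np.allclose(t.min_divergence, t.min_divergence.T)


class TestDiagnosticMask:
    def make_table(self, d):
        from contamkit.barcode import DivergenceTable

        m = np.array([[0.0, d], [d, 0.0]])
        return DivergenceTable(species=["x", "y"], min_divergence=m,
                               unreliable=np.zeros((2, 2), bool))

    def test_below_threshold_nondiagnostic(self):
        assert diagnostic_mask(self.make_table(0.04))[("x", "y")] is False

    def test_above_threshold_diagnostic(self):
        assert diagnostic_mask(self.make_table(0.051))[("x", "y")] is True

    def test_ten_percent_variant_flips_intermediate_pairs(self):
        t = self.make_table(0.07)
        assert diagnostic_mask(t, threshold=0.05)[("x", "y")] is True
        assert diagnostic_mask(t, threshold=0.10)[("x", "y")] is False

    def test_self_pairs_never_diagnostic(self):
        assert diagnostic_mask(self.make_table(0.5))[("x", "x")] is False


class TestMapRead:
    def test_exact_substring_hits(self, rng):
        p = toy_panel()
        read = p.sequences[1][37 : 37 + 50]
        hit = map_read(read, p, rng=rng)
        assert hit is not None and hit.mismatches == 0
        assert hit.species == "spB" and hit.offset == 37 and hit.strand == "+"

    def test_reverse_strand_hit(self, rng):
        p = toy_panel()
        frag = p.sequences[2][10:60]
        rc = frag.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        hit = map_read(rc, p, rng=rng)
        assert hit is not None and hit.species == "spC" and hit.strand == "-"

    def test_tolerance_enforced(self, rng):
        p = toy_panel()
        read = list(p.sequences[0][:50])
        for i in (5, 15, 25):  # 3 mismatches, tolerance for 50 bp is 1
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        assert map_read("".join(read), p, rng=rng) is None
        assert map_read("".join(read), p, max_mismatch=3, rng=rng) is not None

    def test_default_tolerance_by_length(self):
        assert default_max_mismatch(50) == 1
        assert default_max_mismatch(75) == 2
        assert default_max_mismatch(100) == 2

    def test_short_reads_skipped(self, rng):
        assert map_read("ACGTACGT", toy_panel(), rng=rng) is None

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        p = toy_panel()
        for _ in range(60):
            if rng.random() < 0.7:
                src = int(rng.integers(3))
                off = int(rng.integers(len(p.sequences[src]) - 50))
                read = list(p.sequences[src][off : off + 50])
                nerr = int(rng.integers(0, 3))
                for i in rng.choice(50, nerr, replace=False):
                    read[i] = "ACGT"[int(rng.integers(4))]
                read = "".join(read)
            else:
                read = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            best, tie_set = brute_force_map(read, p, 1)
            hit = map_read(read, p, rng=np.random.default_rng(0))
            if best is None:
                assert hit is None
            else:
                assert hit is not None and hit.mismatches == best
                assert (hit.ref_index, hit.strand, hit.offset, hit.mismatches) in tie_set

    def test_tie_break_is_seeded_uniform(self):
        p = ReferencePanel(
            ids=["a", "b"], species=["x", "y"], components=["target"] * 2,
            sequences=["ACGT" * 10, "ACGT" * 10],
        )
        read = "ACGT" * 8
        picks = {map_read(read, p, rng=np.random.default_rng(s)).species
                 for s in range(20)}
        assert picks == {"x", "y"}
        again = [map_read(read, p, rng=np.random.default_rng(3)).ref_index
                 for _ in range(3)]
        assert len(set(again)) == 1


class TestScreenSample:
    def setup_method(self):
        self.exp = simulate_barcode_experiment(
            n_species=6, samples_per_species=1, total_reads_per_sample=2_000_000,
            sequencing_error=0.0,
            scenario=ContaminationScenario(expected_prevalence=5.0),
            seed=8,
        )
        self.mask = diagnostic_mask(pairwise_divergence(self.exp.panel))

    def test_prevalence_normalization(self, rng):
        sample = next(iter(self.exp.reads))
        row = screen_sample(
            self.exp.reads[sample], self.exp.panel, self.exp.expected_species[sample],
            self.mask, total_reads=2_000_000, rng=rng,
        )
        assert row.expected_prevalence == pytest.approx(row.expected_hits / 2.0)

    def test_clean_sample_has_no_unexpected_hits(self, rng):
        for sample, reads in self.exp.reads.items():
            row = screen_sample(
                reads, self.exp.panel, self.exp.expected_species[sample], self.mask,
                total_reads=self.exp.total_reads[sample], rng=rng,
            )
            assert row.unexpected_hits == 0
            assert not row.dubious

    def test_nondiagnostic_hits_not_counted_unexpected(self, rng):
        exp = simulate_barcode_experiment(
            n_species=4, samples_per_species=1, sequencing_error=0.0,
            n_close_pairs=1, close_pair_divergence=0.02,
            scenario=ContaminationScenario(
                expected_prevalence=0.0,
                prevalence_by_relation={"same_shipment": 100.0},
            ),
            metadata_kwargs={"shipment_dates": ["2012-03-01"]},
            seed=9,
        )
        mask = diagnostic_mask(pairwise_divergence(exp.panel))
        # species004 is the close relative of species001
        sample = "species001_ind1"
        row = screen_sample(
            exp.reads[sample], exp.panel, "species001", mask,
            total_reads=exp.total_reads[sample], rng=np.random.default_rng(1),
        )
        assert "species004" not in row.unexpected_by_species
        injected_diag = {
            sp: n for sp, n in exp.truth["injected_reads"][sample].items()
            if mask[("species001", sp)]
        }
        assert row.unexpected_hits >= 0.8 * sum(injected_diag.values())

    def test_zero_reads_rejected(self, rng):
        with pytest.raises(ValueError):
            screen_sample([], self.exp.panel, "species001", self.mask,
                          total_reads=0, rng=rng)

    def test_dubious_flag(self, rng):
        sample = "species001_ind1"
        other = "species002_ind1"
        # feed species002's reads as if they were species001's
        row = screen_sample(
            self.exp.reads[other], self.exp.panel, "species001", self.mask,
            total_reads=2_000_000, rng=rng,
        )
        assert row.dubious


class TestContaminationMatrix:
    def make_rows(self, unexpected):
        from contamkit.barcode import HitTableRow

        rows = []
        for sample, (sp, by_sp) in unexpected.items():
            rows.append(HitTableRow(
                sample=sample, expected_species=sp, total_reads=10 ** 6,
                hits_per_reference={}, hits_per_species={},
                expected_hits=100, unexpected_hits=sum(by_sp.values()),
                nondiagnostic_hits=0, expected_prevalence=100.0,
                unexpected_prevalence=float(sum(by_sp.values())),
                unexpected_by_species=by_sp, dubious=False, expected_in_panel=True,
            ))
        return rows

    def full_mask(self, species):
        return {(a, b): a != b for a in species for b in species}

    def test_single_read_sets_cell(self):
        rows = self.make_rows({"s1": ("x", {"y": 1})})
        M = build_contamination_matrix(rows, self.full_mask(["x", "y"]))
        assert M.cell("y", "x") == 1.0

    def test_min_reads_threshold(self):
        rows = self.make_rows({"s1": ("x", {"y": 4})})
        M1 = build_contamination_matrix(rows, self.full_mask(["x", "y"]), min_reads=1)
        M10 = build_contamination_matrix(rows, self.full_mask(["x", "y"]), min_reads=10)
        assert M1.cell("y", "x") == 1.0
        assert M10.cell("y", "x") == 0.0

    def test_nondiagnostic_pairs_missing(self):
        rows = self.make_rows({"s1": ("x", {"y": 50})})
        mask = self.full_mask(["x", "y"])
        mask[("x", "y")] = mask[("y", "x")] = False
        M = build_contamination_matrix(rows, mask)
        assert np.isnan(M.cell("y", "x"))

    def test_unsampled_species_keep_contaminant_rows(self):
        rows = self.make_rows({"s1": ("x", {"z": 2})})
        M = build_contamination_matrix(rows, self.full_mask(["x", "y", "z"]))
        assert M.cell("z", "x") == 1.0
        assert np.isnan(M.cell("x", "y"))  # y never sampled
        assert np.isnan(M.cell("x", "z"))  # z never sampled

    def test_p_is_share_of_ones(self):
        rows = self.make_rows({"s1": ("x", {"y": 1}), "s2": ("y", {})})
        M = build_contamination_matrix(rows, self.full_mask(["x", "y"]))
        assert M.p == pytest.approx(M.n_ones / M.n_defined)
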