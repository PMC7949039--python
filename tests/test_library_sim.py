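"""Shearing statistics, frame-class truth, and the reporter-selection model."""

import numpy as np
import pytest
from scipy import stats

from domyseq.library_sim import (
    BindingModel,
    Fragment,
    SelectionError,
    ShearModel,
    amplify,
    assign_frame_label,
    is_selected,
    read_fragments_tsv,
    shear_plasmid,
    simulate_selection,
    write_fragments_tsv,
)
from domyseq.reference import FRAME_LABELS, AaInterval, PlasmidMap
from conftest import build_toy_plasmid


@pytest.fixture(scope="module")
def big_library():
    plasmid = build_toy_plasmid(orf_aa=150, length=1500, cds_start=300, seed=5)
    model = ShearModel(mean_len=350, sd_len=88, min_len=100, n_fragments=60_000, seed=11)
    return plasmid, shear_plasmid(plasmid, model)


class TestShear:
    def test_deterministic_for_fixed_seed(self, toy_plasmid):
        model = ShearModel(mean_len=120, sd_len=30, min_len=50, n_fragments=500, seed=4)
        a = shear_plasmid(toy_plasmid, model)
        b = shear_plasmid(toy_plasmid, model)
        assert [(f.start, f.length, f.strand) for f in a] == [
            (f.start, f.length, f.strand) for f in b
        ]

    def test_start_positions_uniform(self, big_library):
        plasmid, frags = big_library
        starts = np.array([f.start for f in frags])
        counts, _ = np.histogram(starts, bins=100, range=(0, plasmid.length))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_mean_length_within_one_percent(self, big_library):
        _, frags = big_library
        mean = np.mean([f.length for f in frags])
        assert abs(mean - 350) / 350 < 0.01

    def test_lengths_respect_floor(self, big_library):
        _, frags = big_library
        assert min(f.length for f in frags) >= 100

    def test_strands_balanced(self, big_library):
        _, frags = big_library
        plus = sum(f.strand == "+" for f in frags) / len(frags)
        assert abs(plus - 0.5) < 0.01

    def test_empty_library_warns(self, toy_plasmid):
        with pytest.warns(UserWarning):
            assert shear_plasmid(toy_plasmid, ShearModel(n_fragments=0)) == []

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            ShearModel(min_len=0)
        with pytest.raises(ValueError):
            ShearModel(mean_len=10, min_len=20)


class TestFrameTruth:
    def test_exactly_six_classes(self, toy_plasmid):
        # exhaustive enumeration over (offset x strand)
        labels = {
            assign_frame_label(
                Fragment("f", toy_plasmid.cds_start + off, 30, strand), toy_plasmid
            )
            for off in range(3)
            for strand in "+-"
        }
        assert labels == set(FRAME_LABELS)

    def test_coding_offset_is_plus2(self, toy_plasmid):
        f = Fragment("f", toy_plasmid.cds_start + 9, 30, "+")
        assert assign_frame_label(f, toy_plasmid) == "+2"

    def test_unselected_fractions_near_one_sixth(self, big_library):
        _, frags = big_library
        counts = {lab: 0 for lab in FRAME_LABELS}
        for f in frags[:10_000]:
            counts[f.frame_label] += 1
        expected = 10_000 / 6
        assert stats.chisquare(list(counts.values())).pvalue > 0.01
        for c in counts.values():
            assert abs(c - expected) / 10_000 < 0.02


def _coding_fragment(plasmid, first_res, last_res, extra_nt=0):
    """In-frame fragment exactly covering residues first..last (+extra nt)."""
    start = plasmid.cds_start + 3 * (first_res - 1)
    length = 3 * (last_res - first_res + 1) + extra_nt
    f = Fragment("f", start, length, "+")
    f.frame_label = assign_frame_label(f, plasmid)
    return f


class TestSelection:
    @pytest.fixture
    def setup(self):
        plasmid = build_toy_plasmid(orf_aa=100, length=700, cds_start=120, seed=3)
        binding = BindingModel(true_interval=AaInterval(30, 50))
        return plasmid, binding, np.random.default_rng(0)

    def test_covering_coding_fragment_selected(self, setup):
        plasmid, binding, rng = setup
        f = _coding_fragment(plasmid, 25, 60)
        assert is_selected(f, plasmid, binding, rng) == (True, "binding")

    def test_out_of_frame_not_selected(self, setup):
        plasmid, binding, rng = setup
        f = Fragment("f", plasmid.cds_start + 3 * 24 + 1, 110, "+")
        assert is_selected(f, plasmid, binding, rng) == (False, "none")

    def test_antisense_not_selected(self, setup):
        plasmid, binding, rng = setup
        f = Fragment("f", plasmid.cds_start + 3 * 24, 110, "-")
        assert is_selected(f, plasmid, binding, rng) == (False, "none")

    def test_partial_coverage_needs_stringency(self, setup):
        plasmid, binding, rng = setup
        f = _coding_fragment(plasmid, 30, 40)  # covers only part of 30..50
        assert is_selected(f, plasmid, binding, rng) == (False, "none")
        leaky = BindingModel(true_interval=AaInterval(30, 50), coverage_stringency=1.0)
        assert is_selected(f, plasmid, leaky, rng) == (True, "binding")

    def test_short_fragment_never_binding(self, setup):
        # shorter than 3 x interval width: cannot cover the motif
        plasmid, binding, rng = setup
        for start in range(0, plasmid.length, 17):
            f = Fragment("f", start, 3 * 21 - 3, "+")
            ok, cause = is_selected(f, plasmid, binding, rng)
            assert cause != "binding"

    def test_forbidden_interval_abolishes(self, setup):
        plasmid, _, rng = setup
        binding = BindingModel(
            true_interval=AaInterval(30, 50), forbidden_interval=AaInterval(55, 60)
        )
        assert is_selected(_coding_fragment(plasmid, 25, 54), plasmid, binding, rng)[0]
        assert not is_selected(_coding_fragment(plasmid, 25, 56), plasmid, binding, rng)[0]

    def test_tad_self_activation(self, setup):
        plasmid, _, rng = setup
        binding = BindingModel(tad_intervals=(AaInterval(70, 78),))
        f = _coding_fragment(plasmid, 65, 85)
        assert is_selected(f, plasmid, binding, rng) == (True, "self_activation")

    def test_stop_codon_upstream_kills_selection(self):
        # backbone engineered with an in-frame stop just before the ORF
        plasmid = build_toy_plasmid(orf_aa=100, length=700, cds_start=120, seed=3)
        seq = plasmid.sequence
        stop_at = plasmid.cds_start - 6  # on the codon grid
        seq = seq[:stop_at] + "TAA" + seq[stop_at + 3 :]
        plasmid = PlasmidMap("pSTOP", seq, cds_start=120, cds_aa_length=100)
        binding = BindingModel(true_interval=AaInterval(2, 10))
        rng = np.random.default_rng(0)
        inside = Fragment("a", plasmid.cds_start, 60, "+")
        crossing = Fragment("b", stop_at, 90, "+")
        assert is_selected(inside, plasmid, binding, rng) == (True, "binding")
        assert is_selected(crossing, plasmid, binding, rng) == (False, "none")

    def test_background_rate_one_selects_everything(self, setup):
        plasmid, _, rng = setup
        binding = BindingModel(background_rate=1.0)
        f = Fragment("f", 5, 40, "-")
        assert is_selected(f, plasmid, binding, rng) == (True, "background")

    def test_stringency_monotone_under_coupled_randomness(self):
        plasmid = build_toy_plasmid(orf_aa=100, length=700, cds_start=120, seed=9)
        frags = shear_plasmid(
            plasmid, ShearModel(mean_len=150, sd_len=40, min_len=60, n_fragments=4000, seed=2)
        )
        counts = {}
        for s in (0.2, 0.5, 0.9):
            binding = BindingModel(true_interval=AaInterval(30, 50), coverage_stringency=s)
            sel, _ = simulate_selection([Fragment(**f.__dict__) for f in frags], plasmid, binding, seed=77)
            counts[s] = len(sel)
        assert counts[0.2] <= counts[0.5] <= counts[0.9]


class TestSimulateSelection:
    def test_noise_free_selection_is_all_coding(self):
        plasmid = build_toy_plasmid(orf_aa=100, length=700, cds_start=120, seed=3)
        frags = shear_plasmid(
            plasmid, ShearModel(mean_len=200, sd_len=50, min_len=80, n_fragments=8000, seed=2)
        )
        binding = BindingModel(true_interval=AaInterval(30, 50))
        sel, summary = simulate_selection(frags, plasmid, binding, seed=0)
        assert sel and all(f.frame_label == "+2" for f in sel)
        assert summary.by_cause["binding"] == len(sel)
        assert summary.by_cause["self_activation"] == summary.by_cause["background"] == 0

    def test_summary_deterministic(self):
        plasmid = build_toy_plasmid(orf_aa=100, length=700, cds_start=120, seed=3)
        model = ShearModel(mean_len=200, sd_len=50, min_len=80, n_fragments=4000, seed=2)
        binding = BindingModel(true_interval=AaInterval(30, 50), background_rate=0.01)
        runs = []
        for _ in range(2):
            frags = shear_plasmid(plasmid, model)
            sel, summary = simulate_selection(frags, plasmid, binding, seed=5)
            runs.append(([f.id for f in sel], summary.by_cause, summary.by_frame))
        assert runs[0] == runs[1]

    def test_empty_selection_raises(self, toy_plasmid):
        frags = shear_plasmid(
            toy_plasmid, ShearModel(mean_len=60, sd_len=5, min_len=50, n_fragments=50, seed=1)
        )
        binding = BindingModel(true_interval=AaInterval(1, 100))  # unreachable
        with pytest.raises(SelectionError):
            simulate_selection(frags, toy_plasmid, binding, seed=0)

    def test_selected_spans_contain_truth(self):
        from domyseq.reference import residue_span

        plasmid = build_toy_plasmid(orf_aa=100, length=700, cds_start=120, seed=3)
        frags = shear_plasmid(
            plasmid, ShearModel(mean_len=200, sd_len=50, min_len=80, n_fragments=8000, seed=2)
        )
        truth = AaInterval(30, 50)
        sel, _ = simulate_selection(frags, plasmid, BindingModel(true_interval=truth), seed=0)
        for f in sel:
            assert residue_span(plasmid, f.start, f.length).contains(truth)


def test_amplify_and_tsv_round_trip(toy_plasmid, tmp_path):
    frags = shear_plasmid(
        toy_plasmid, ShearModel(mean_len=120, sd_len=30, min_len=50, n_fragments=40, seed=4)
    )
    amped = amplify(frags, mean_copies=3.0, rng=np.random.default_rng(1))
    assert sum(f.copies for f in amped) > len(frags)
    path = tmp_path / "frags.tsv"
    write_fragments_tsv(amped, toy_plasmid, path, header_lines=["seed=4"])
    back = read_fragments_tsv(path)
    assert [(f.id, f.start, f.length, f.strand, f.frame_label, f.copies) for f in back] == [
        (f.id, f.start, f.length, f.strand, f.frame_label, f.copies) for f in amped
    ]
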