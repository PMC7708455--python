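"""Identification engine tests: filtering, search, scoring, FDR."""

import itertools

import numpy as np
import pytest

from glycotyper.chem import (
    AA_RESIDUE_MASS,
    ITRAQ4PLEX,
    PROTON_MASS,
    WATER_MASS,
    GlycanComposition,
    GlycositePeptide,
)
from glycotyper.ident import (
    GlycoPSM,
    GlycoSearchEngine,
    Spectrum,
    assign_best,
    fdr_filter,
    is_oxo_spectrum,
    make_decoys,
    mass_gap_candidates,
    morpheus_score,
    search_spectra,
    theoretical_fragments,
)

OXO = 204.0966


def make_spectrum(mz, intensity, spectrum_id="s1", precursor_mz=1000.0, charge=2):
    return Spectrum(spectrum_id, precursor_mz, charge,
                    np.asarray(mz, float), np.asarray(intensity, float))


class TestOxoFilter:
    def test_oxonium_in_top_peaks(self):
        mz = [300.0, 400.0, OXO, 500.0]
        intensity = [100, 90, 80, 70]
        assert is_oxo_spectrum(make_spectrum(mz, intensity))

    def test_oxonium_ranked_eleventh_is_missed(self):
        mz = [OXO] + [300.0 + i for i in range(11)]
        intensity = [1.0] + [10.0 + i for i in range(11)]
        assert not is_oxo_spectrum(make_spectrum(mz, intensity))

    @pytest.mark.parametrize("ppm, expected", [(19.0, True), (21.0, False)])
    def test_ppm_window_boundary(self, ppm, expected):
        # brute-force interval check: |mz - oxo| vs 20e-6 * oxo
        peak = OXO * (1 + ppm * 1e-6)
        assert (abs(peak - OXO) <= 20e-6 * OXO) is expected
        s = make_spectrum([peak], [100.0])
        assert is_oxo_spectrum(s) is expected

    def test_reporter_region_excluded_from_ranking(self):
        # ten huge reporter-region peaks must not push the oxonium out of the top 10
        mz = [114.0 + 0.1 * i for i in range(10)] + [OXO] + [400.0 + i for i in range(9)]
        intensity = [1e9] * 10 + [1.0] + [10.0] * 9
        assert is_oxo_spectrum(make_spectrum(mz, intensity))

    def test_empty_spectrum_is_not_oxo(self):
        assert not is_oxo_spectrum(make_spectrum([], []))


@pytest.fixture(scope="module")
def tiny_db():
    peptides = [
        GlycositePeptide("NASK", 0, "P1"),
        GlycositePeptide("LNSTAK", 1, "P2"),
        GlycositePeptide("ANATFVR", 1, "P3"),
    ]
    glycans = [
        GlycanComposition(5, 2, 0, 0),
        GlycanComposition(5, 4, 1, 0),
        GlycanComposition(5, 4, 1, 2),
    ]
    return peptides, glycans


class TestMassGapSearch:
    def test_planted_pair_is_unique_hit(self, tiny_db):
        peptides, glycans = tiny_db
        pep, gly = peptides[1], glycans[2]
        z = 2
        mz = (pep.backbone_mass + gly.residue_mass + z * PROTON_MASS) / z
        s = make_spectrum([500.0], [1.0], precursor_mz=mz, charge=z)
        hits = mass_gap_candidates(s, peptides, glycans)
        assert hits == [(pep, gly)]

    def test_no_match_returns_empty(self, tiny_db):
        peptides, glycans = tiny_db
        s = make_spectrum([500.0], [1.0], precursor_mz=123.4, charge=1)
        assert mass_gap_candidates(s, peptides, glycans) == []

    def test_two_glycans_inside_tolerance_both_returned(self, tiny_db):
        peptides, _ = tiny_db
        # two compositions whose masses differ by less than the (widened)
        # tolerance window around the precursor
        g1 = GlycanComposition(5, 4, 2, 0)  # 2 x Fuc = 292.1158
        g2 = GlycanComposition(5, 4, 0, 1)  # 1 x NeuAc = 291.0954
        pep = peptides[0]
        z = 2
        mid = pep.backbone_mass + (g1.residue_mass + g2.residue_mass) / 2
        s = make_spectrum([500.0], [1.0], precursor_mz=(mid + z * PROTON_MASS) / z,
                          charge=z)
        hits = mass_gap_candidates(s, peptides, [g1, g2], precursor_tol_ppm=400)
        assert {h[1] for h in hits} == {g1, g2}

    def test_engine_equals_exhaustive_cross_product(self, small_spectra_sim):
        peptides = small_spectra_sim.peptides[:50]
        glycans = small_spectra_sim.glycans[:40]
        engine = GlycoSearchEngine(peptides, glycans)
        for s in small_spectra_sim.spectra[:40]:
            assert engine.candidates(s) == mass_gap_candidates(s, peptides, glycans)

    def test_empty_databases(self, tiny_db):
        peptides, glycans = tiny_db
        s = make_spectrum([500.0], [1.0])
        assert mass_gap_candidates(s, [], glycans) == []
        assert mass_gap_candidates(s, peptides, []) == []


class TestTheoreticalFragments:
    def test_bare_peptide_gives_by_series(self):
        p = GlycositePeptide("NASK", 0, "P1")
        frags = theoretical_fragments(p, GlycanComposition(), max_charge=1, n_isotopes=0)
        # b1, b2, b3 and y1, y2, y3, plus Y0 (= precursor MH+) and oxonium set
        y1 = AA_RESIDUE_MASS["K"] + ITRAQ4PLEX + WATER_MASS + PROTON_MASS
        assert np.min(np.abs(frags - y1)) < 1e-9

    def test_y1_hand_summed(self):
        p = GlycositePeptide("NK", 0, "P1")
        frags = theoretical_fragments(p, GlycanComposition(), max_charge=1, n_isotopes=0)
        expected = AA_RESIDUE_MASS["K"] + WATER_MASS + PROTON_MASS + 144.102063
        assert np.min(np.abs(frags - expected)) < 1e-5

    def test_duplicate_free(self, tiny_db):
        peptides, glycans = tiny_db
        for p, g in itertools.product(peptides, glycans):
            frags = theoretical_fragments(p, g)
            assert np.all(np.diff(frags) > 1e-6)

    def test_glycan_adds_y_series(self, tiny_db):
        peptides, glycans = tiny_db
        p = peptides[0]
        bare = theoretical_fragments(p, GlycanComposition(), max_charge=1, n_isotopes=0)
        full = theoretical_fragments(p, glycans[0], max_charge=1, n_isotopes=0)
        assert full.size > bare.size
        # the full glycopeptide MH+ is present
        mh = p.backbone_mass + glycans[0].residue_mass + PROTON_MASS
        assert np.min(np.abs(full - mh)) < 1e-9


def _optimal_matching(mz, intensity, fragments, tol_ppm):
    """Exhaustive assignment oracle: maximum number of peak<->fragment matches."""
    edges = [
        (i, j)
        for i, m in enumerate(mz)
        for j, f in enumerate(fragments)
        if abs(m - f) <= f * tol_ppm * 1e-6
    ]

    best = 0
    def extend(used_p, used_f, k, count):
        nonlocal best
        best = max(best, count)
        for idx in range(k, len(edges)):
            i, j = edges[idx]
            if i not in used_p and j not in used_f:
                extend(used_p | {i}, used_f | {j}, idx + 1, count + 1)

    extend(frozenset(), frozenset(), 0, 0)
    return best


class TestMorpheusScore:
    def test_no_match(self):
        s = make_spectrum([500.0, 600.0], [10.0, 20.0])
        score, n, frac = morpheus_score(s, np.array([900.0]))
        assert (score, n, frac) == (0.0, 0, 0.0)

    def test_perfect_match_of_eight_fragments(self):
        frags = np.array([300.0 + 10 * i for i in range(8)])
        s = make_spectrum(frags, np.full(8, 5.0))
        score, n, frac = morpheus_score(s, frags)
        assert n == 8
        assert frac == pytest.approx(1.0)
        assert score == pytest.approx(9.0)

    def test_score_is_count_plus_fraction(self):
        frags = np.array([300.0, 400.0])
        s = make_spectrum([300.0, 400.0, 700.0], [30.0, 30.0, 40.0])
        score, n, frac = morpheus_score(s, frags)
        assert n == 2
        assert frac == pytest.approx(0.6)
        assert score == pytest.approx(2.6)

    def test_greedy_equals_exhaustive_on_small_instances(self, rng):
        for _ in range(60):
            n_peaks = int(rng.integers(1, 7))
            mz = np.sort(rng.uniform(200, 1200, n_peaks))
            intensity = rng.uniform(1, 100, n_peaks)
            frags = np.sort(rng.uniform(200, 1200, int(rng.integers(1, 8))))
            s = make_spectrum(mz, intensity)
            _, n_matched, _ = morpheus_score(s, frags, frag_tol_ppm=3000)
            assert n_matched == _optimal_matching(mz, intensity, frags, 3000)

    def test_noise_never_raises_intensity_fraction(self, rng):
        frags = np.array([300.0, 400.0, 500.0])
        s = make_spectrum(frags, np.full(3, 10.0))
        _, _, base_frac = morpheus_score(s, frags)
        for _ in range(10):
            extra = rng.uniform(600, 1200, 5)
            noisy = make_spectrum(
                np.concatenate([frags, extra]),
                np.concatenate([np.full(3, 10.0), rng.uniform(1, 50, 5)]),
            )
            _, _, frac = morpheus_score(noisy, frags)
            assert frac <= base_frac + 1e-12

    def test_zero_intensity_errors(self):
        s = make_spectrum([115.0], [5.0])  # only reporter-region signal
        with pytest.raises(ValueError):
            morpheus_score(s, np.array([300.0]))


def _spectrum_from_fragments(pep, gly, n_fragments, spectrum_id="sx"):
    frags = theoretical_fragments(pep, gly, max_charge=1, n_isotopes=0)
    frags = frags[frags >= 250.0][:n_fragments]
    z = 2
    mz = (pep.backbone_mass + gly.residue_mass + z * PROTON_MASS) / z
    return Spectrum(spectrum_id, mz, z, frags, np.full(frags.size, 10.0))


class TestAssignBest:
    def test_single_candidate_with_seven_matches(self, tiny_db):
        peptides, glycans = tiny_db
        pep, gly = peptides[2], glycans[0]
        s = _spectrum_from_fragments(pep, gly, 7)
        psm = assign_best(s, [(pep, gly)])
        assert psm is not None
        assert psm.n_matched_fragments == 7

    def test_six_matches_excluded(self, tiny_db):
        peptides, glycans = tiny_db
        pep, gly = peptides[2], glycans[0]
        s = _spectrum_from_fragments(pep, gly, 6)
        assert assign_best(s, [(pep, gly)]) is None

    def test_higher_scoring_candidate_wins(self, tiny_db):
        peptides, glycans = tiny_db
        pep, gly = peptides[2], glycans[0]
        s = _spectrum_from_fragments(pep, gly, 10)
        other = (peptides[0], glycans[1])
        psm = assign_best(s, [other, (pep, gly)])
        assert psm.peptide == pep

    def test_tie_break_is_deterministic(self, tiny_db):
        _, glycans = tiny_db
        pep_a = GlycositePeptide("ANATFVR", 1, "PA")
        pep_b = GlycositePeptide("ANATFVR", 1, "PB")  # identical mass & fragments
        s = _spectrum_from_fragments(pep_a, glycans[0], 10)
        for _ in range(3):
            psm = assign_best(s, [(pep_b, glycans[0]), (pep_a, glycans[0])])
            assert psm.peptide.protein_id == "PA"


def _psm(score, frac, decoy, i):
    pep = GlycositePeptide("NASK", 0, f"{'DECOY_' if decoy else ''}P{i:04d}")
    return GlycoPSM(f"s{i:04d}", pep, GlycanComposition(5, 2, 0, 0),
                    score, int(score), frac, is_decoy=decoy)


class TestFdrFilter:
    def test_decoy_boundary_q_values(self):
        # 99 clean targets, then a block of 10 decoys, then 20 weaker targets:
        # q at rank 100 = 1/99 ~ 0.0101, so nothing past the boundary survives 1% FDR
        psms = [_psm(1000.0 - i, 0.5, False, i) for i in range(99)]
        psms += [_psm(800.0 - i, 0.5, True, 99 + i) for i in range(10)]
        psms += [_psm(700.0 - i, 0.5, False, 200 + i) for i in range(20)]
        accepted = fdr_filter(psms, fdr_threshold=0.01)
        assert len(accepted) == 99
        first_decoy = next(p for p in psms if p.is_decoy)
        assert first_decoy.q_value == pytest.approx(1 / 99, abs=1e-9)
        tail_targets = [p for p in psms if not p.is_decoy and p.morpheus_score < 800]
        assert all(p.q_value >= 0.01 for p in tail_targets)
        assert all(p.q_value == 0.0 for p in accepted)

    def test_all_targets_accepted_when_no_decoy_scores(self):
        psms = [_psm(100.0 - i, 0.5, False, i) for i in range(10)]
        accepted = fdr_filter(psms)
        assert len(accepted) == 10
        assert all(p.q_value == 0.0 for p in accepted)

    def test_intensity_fraction_boundary_is_strict(self):
        ok = _psm(50.0, 0.101, False, 0)
        boundary = _psm(49.0, 0.10, False, 1)
        accepted = fdr_filter([ok, boundary])
        assert accepted == [ok]

    def test_search_without_decoys_errors(self, small_spectra_sim):
        with pytest.raises(ValueError, match="decoy"):
            search_spectra(small_spectra_sim.spectra[:2], small_spectra_sim.peptides,
                           small_spectra_sim.glycans, with_decoys=False)


class TestDecoys:
    def test_reversal_and_site_mirroring(self):
        p = GlycositePeptide("ANATFVR", 1, "P1")
        (d,) = make_decoys([p])
        assert d.sequence == "RVFTANA"
        assert d.glycosite_index == 5
        assert d.protein_id == "DECOY_P1"
        assert d.sequence[d.glycosite_index] == "N"

    def test_palindrome_skipped(self):
        p = GlycositePeptide("ANA", 1, "P1")
        assert make_decoys([p]) == []


class TestEndToEnd:
    def test_recovery_on_synthetic_spectra(self, small_spectra_sim):
        res = small_spectra_sim
        accepted, best = search_spectra(res.spectra, res.peptides, res.glycans)
        truth = res.truth.set_index("spectrum_id")
        correct = sum(
            truth.loc[p.spectrum_id, "sequence"] == p.peptide.sequence
            and tuple(truth.loc[p.spectrum_id, ["hex", "hexnac", "fuc", "neuac"]])
            == p.glycan.as_tuple()
            for p in accepted
        )
        n_glyco = int(truth["is_glyco"].sum())
        assert correct / n_glyco >= 0.9
        assert (len(accepted) - correct) / max(len(accepted), 1) <= 0.02

    def test_psm_table_is_deterministic(self, small_spectra_sim, tmp_path):
        from glycotyper.io import write_psm_table

        res = small_spectra_sim
        outputs = []
        for run in range(2):
            accepted, _ = search_spectra(res.spectra, res.peptides, res.glycans)
            path = tmp_path / f"psms_{run}.tsv"
            write_psm_table(accepted, path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]
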