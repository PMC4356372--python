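"""Helix building, refinement, isosteric variants, base-pair detection."""

import numpy as np
import pytest

from nucleofit.builder import (
    build_restraints,
    choose_isosteric_variant,
    detect_base_pairs,
    extend_with_loops,
    merge_fragments,
    place_helices,
    refine_fragment,
    rscc,
    score_fit,
    _objective,
)
from nucleofit.crystal_maps import (
    DensityMap,
    SymmetryOps,
    UnitCell,
    bias_phases,
    compute_structure_factors,
    min_symmetry_distance,
    synthesize_map,
)
from nucleofit.fiber import HelixSpec, Motif, generate_helix
from nucleofit.motifs import default_library
from nucleofit.phosphate_detect import PhosphateSet

from conftest import relaxed_recovery


def _residue_atom(model, chain, resseq, name):
    mask = (model.chain == chain) & (model.resseq == resseq) & \
        (model.name == name)
    return model.xyz[mask][0]


class TestScoring:
    def test_zero_map_scores_zero(self, helix_crystal):
        truth, cell = helix_crystal
        zero = DensityMap(np.zeros((16, 16, 16)), cell, normalized=False)
        assert score_fit(truth, zero) == 0.0

    def test_true_pose_beats_translated(self, helix_crystal, helix_map_good):
        truth, _cell = helix_crystal
        shifted = truth.transformed(np.eye(3), np.array([3.0, 0.0, 0.0]))
        assert score_fit(truth, helix_map_good) > \
            score_fit(shifted, helix_map_good)

    def test_score_additive_over_atoms(self, helix_crystal, helix_map_good):
        truth, _cell = helix_crystal
        half = len(truth) // 2
        mask = np.arange(len(truth)) < half
        total = score_fit(truth, helix_map_good)
        parts = score_fit(truth.select(mask), helix_map_good) + \
            score_fit(truth.select(~mask), helix_map_good)
        assert total == pytest.approx(parts, rel=1e-9)


class TestRSCC:
    def test_self_consistency(self, helix_crystal, helix_map_good):
        truth, _cell = helix_crystal
        assert rscc(truth, helix_map_good) > 0.9

    def test_uncorrelated_noise_map_near_zero(self, helix_crystal):
        truth, cell = helix_crystal
        rng = np.random.default_rng(0)
        vals = []
        for rep in range(10):
            noise = DensityMap(rng.normal(0, 1, (48, 48, 48)), cell,
                               normalized=True, info={"d_min": 2.5})
            vals.append(abs(rscc(truth, noise)))
        assert max(vals) < 0.2

    def test_invariant_under_affine_map_rescaling(self, helix_crystal,
                                                  helix_map_good):
        truth, _cell = helix_crystal
        import dataclasses

        scaled = dataclasses.replace(helix_map_good)
        scaled.grid = 3.7 * helix_map_good.grid + 11.0
        assert rscc(truth, scaled) == pytest.approx(
            rscc(truth, helix_map_good), abs=1e-9)

    def test_zero_variance_region_errors(self, helix_crystal):
        truth, cell = helix_crystal
        flat = DensityMap(np.zeros((24, 24, 24)), cell, normalized=True,
                          info={"d_min": 3.0})
        with pytest.raises(ValueError):
            rscc(truth, flat)


class TestRefinement:
    def test_refinement_never_worsens_objective(self, helix_crystal,
                                                helix_map_good):
        truth, _cell = helix_crystal
        start = truth.transformed(np.eye(3), np.array([0.8, -0.4, 0.5]))
        restraints = build_restraints(start)
        refined, _conv = refine_fragment(start, helix_map_good, restraints)
        before = -_objective(start.xyz.ravel(), helix_map_good, restraints,
                             len(start), 1.0)[0]
        after = -_objective(refined.xyz.ravel(), helix_map_good, restraints,
                            len(refined), 1.0)[0]
        assert after >= before - 1e-6

    def test_displaced_fragment_moves_back_towards_truth(self, helix_crystal,
                                                         helix_map_good):
        truth, _cell = helix_crystal
        start = truth.transformed(np.eye(3), np.array([1.0, 0.0, 0.0]))
        refined, _conv = refine_fragment(start, helix_map_good)
        rmsd0 = np.sqrt(((start.xyz - truth.xyz) ** 2).sum(axis=1).mean())
        rmsd1 = np.sqrt(((refined.xyz - truth.xyz) ** 2).sum(axis=1).mean())
        assert rmsd1 < rmsd0
        assert rmsd1 < 0.5

    def test_local_optimum_is_stable(self, helix_crystal, helix_map_good):
        truth, _cell = helix_crystal
        restraints = build_restraints(truth)
        once, _ = refine_fragment(truth, helix_map_good, restraints,
                                  rigid_first=False, max_iter=2000)
        twice, _ = refine_fragment(once, helix_map_good, restraints,
                                   rigid_first=False, max_iter=2000)
        rmsd = np.sqrt(((twice.xyz - once.xyz) ** 2).sum(axis=1).mean())
        assert rmsd < 1e-3

    def test_pure_restraints_restore_ideal_pair_geometry(self, helix_crystal,
                                                         helix_map_good):
        # with the density term off, refinement drives hydrogen bonds to
        # their 2.9 A target
        motif = generate_helix(HelixSpec("A-RNA", 4, "GCGC"))
        frag = motif.fragment
        restraints = build_restraints(frag,
                                      pair_annotations=motif.pair_annotations)
        rng = np.random.default_rng(1)
        import dataclasses

        noisy = dataclasses.replace(frag)
        noisy.xyz = frag.xyz + rng.normal(0, 0.05, frag.xyz.shape)
        refined, _ = refine_fragment(noisy, helix_map_good, restraints,
                                     density_weight=0.0, rigid_first=False,
                                     max_iter=500)
        d = np.linalg.norm(_residue_atom(refined, "A", 1, "N1")
                           - _residue_atom(refined, "B", 4, "N3"))
        assert abs(d - 2.9) < 0.1

    def test_bonded_geometry_preserved(self, helix_crystal, helix_map_good):
        truth, _cell = helix_crystal
        restraints = build_restraints(truth)
        refined, _ = refine_fragment(truth, helix_map_good, restraints)
        bonded = [(i, j, d0) for i, j, d0, k in restraints if d0 < 1.8]
        devs = [abs(np.linalg.norm(refined.xyz[i] - refined.xyz[j]) - d0)
                for i, j, d0 in bonded]
        assert max(devs) < 0.05


class TestBasePairs:
    def test_ideal_helix_pairs_detected_as_wc(self):
        frag = generate_helix(HelixSpec("A-RNA", 4, "GAUC")).fragment
        pairs = detect_base_pairs(frag)
        wc = [(p["res_i"], p["res_j"]) for p in pairs if p["type"] == "WC"]
        expected = {(("A", i), ("B", 5 - i)) for i in range(1, 5)}
        got = {tuple(sorted([a, b])) for a, b in wc}
        assert {tuple(sorted(e)) for e in expected} <= got

    def test_distant_residues_not_paired(self):
        frag = generate_helix(HelixSpec("A-RNA", 3)).fragment
        mask = (frag.chain == "A") & np.isin(frag.resseq, [1])
        far = frag.select(mask).transformed(np.eye(3), np.array([30.0, 0, 0]))
        two = frag.select((frag.chain == "B") & (frag.resseq == 3)).concat(far)
        assert detect_base_pairs(two) == []

    def test_sheared_purine_purine_pair_is_noncanonical(self):
        # G placed against A with sugar-edge contacts: geometrically a
        # pair, but not Watson-Crick
        from nucleofit.fiber import BASE_FRAME

        rows = []
        for name, x, y, z in BASE_FRAME["G"]:
            rows.append((name[0], name, "G", 1, "A", (x, y, z), 20.0, 1.0))
        flip = np.diag([1.0, -1.0, -1.0])
        shift = np.array([1.1, 0.6, 0.0])  # slide breaks the W-C register
        for name, x, y, z in BASE_FRAME["A"]:
            pos = flip @ np.array([x, y, z]) + shift
            rows.append((name[0], name, "A", 2, "B", tuple(pos), 20.0, 1.0))
        from nucleofit.crystal_maps import AtomicModel

        frag = AtomicModel.from_rows(rows)
        pairs = detect_base_pairs(frag)
        assert pairs and all(p["type"] == "noncanonical" for p in pairs)


class TestIsostericVariants:
    def _pair_map(self, letter1, letter2, cell):
        motif = generate_helix(HelixSpec("A-RNA", 4,
                                         f"G{letter1}GC"[:4]))
        # put the probe pair at position 2
        seq = list("GCGC")
        seq[1] = letter1
        motif = generate_helix(HelixSpec("A-RNA", 4, "".join(seq)))
        frag = motif.fragment.transformed(np.eye(3),
                                          np.array([18.0, 18.0, 12.0]))
        refl = compute_structure_factors(frag, cell, d_min=2.5)
        return frag, synthesize_map(refl)

    def test_gc_map_selects_gc(self):
        cell = UnitCell(36, 36, 36)
        frag, dmap = self._pair_map("C", "G", cell)
        out = choose_isosteric_variant(frag, (("A", 2), ("B", 3)), dmap)
        idx = (out.chain == "A") & (out.resseq == 2)
        assert str(out.resname[idx][0]) == "C"  # pyrimidine strand stays C
        idxB = (out.chain == "B") & (out.resseq == 3)
        assert str(out.resname[idxB][0]) == "G"

    def test_flat_map_tie_prefers_gc(self, helix_crystal):
        _truth, cell = helix_crystal
        motif = generate_helix(HelixSpec("A-RNA", 4, "GAGC"))
        frag = motif.fragment.transformed(np.eye(3),
                                          np.array([20.0, 20.0, 20.0]))
        flat = DensityMap(np.zeros((24, 24, 24)) + 0.5, cell,
                          normalized=False, info={"d_min": 3.0})
        out = choose_isosteric_variant(frag, (("A", 2), ("B", 3)), flat)
        idx = (out.chain == "A") & (out.resseq == 2)
        assert str(out.resname[idx][0]) == "G"

    def test_backbone_and_c1_unchanged(self, helix_map_good, helix_crystal):
        truth, _cell = helix_crystal
        c1_before = {
            (c, r): _residue_atom(truth, c, r, "C1'")
            for c, r, _ in truth.residues()
        }
        out = choose_isosteric_variant(truth, (("A", 2), ("B", 7)),
                                       helix_map_good)
        for (c, r), pos in c1_before.items():
            assert np.linalg.norm(_residue_atom(out, c, r, "C1'") - pos) < 0.2

    def test_non_wc_pair_rejected(self, helix_map_good, helix_crystal):
        truth, _cell = helix_crystal
        with pytest.raises(ValueError):
            # two purines cannot form the tested W-C variants
            choose_isosteric_variant(truth, (("A", 1), ("A", 3)),
                                     helix_map_good)


class TestPlaceHelices:
    def test_empty_phosphates_empty_result(self, helix_map_good):
        out = place_helices(helix_map_good, PhosphateSet(np.empty((0, 3))),
                            "A-RNA")
        assert out == []

    def test_planted_duplex_recovered(self, helix_crystal, helix_map_good,
                                      helix_phosphates):
        truth, _cell = helix_crystal
        frags = place_helices(helix_map_good, helix_phosphates, "A-RNA")
        assert frags
        assert all(f.rscc >= 0.5 for f in frags)
        built = merge_fragments(frags)
        assert relaxed_recovery(built, truth) >= 0.8

    def test_every_fragment_has_six_or_more_nucleotides(self, helix_crystal,
                                                        helix_map_good,
                                                        helix_phosphates):
        frags = place_helices(helix_map_good, helix_phosphates, "A-RNA")
        # the length schedule bottoms out at 3 bp, so every placed duplex
        # spans at least 6 nucleotides (duplicate removal may trim copies
        # of already-built ones from the emitted model)
        for f in frags:
            assert len(f.motif.pair_annotations) >= 3

    def test_no_duplicate_phosphates_in_output(self, helix_crystal,
                                               helix_map_good,
                                               helix_phosphates):
        truth, cell = helix_crystal
        frags = place_helices(helix_map_good, helix_phosphates, "A-RNA")
        built = merge_fragments(frags)
        ps = built.xyz[built.name == "P"]
        for i in range(len(ps)):
            others = np.delete(ps, i, axis=0)
            if len(others):
                d = min_symmetry_distance(ps[i], others, cell,
                                          SymmetryOps.p1())
                assert d[0] >= 1.5


class TestLoops:
    def test_no_compatible_flank_gives_empty(self, helix_map_good,
                                             helix_crystal,
                                             helix_phosphates):
        frags = place_helices(helix_map_good, helix_phosphates, "A-RNA")
        bare = Motif(fragment=default_library()[0].fragment,
                     p_pattern=default_library()[0].p_pattern,
                     flanking_pairs=[], tag="no-flanks")
        out = extend_with_loops(frags, [bare], helix_map_good,
                                helix_phosphates)
        assert out == []

    def test_planted_stemloop_recovery(self, stemloop_crystal):
        crystal = stemloop_crystal
        refl = crystal.reflections(2.5)
        dmap = synthesize_map(bias_phases(refl, 18.0, seed=4).reflections)
        phos = PhosphateSet(crystal.reference_p)
        stems = place_helices(dmap, phos, "A-RNA")
        assert stems
        loops = extend_with_loops(stems, default_library(), dmap, phos)
        assert loops
        best = max(loops, key=lambda f: f.density_score)
        assert "tetraloop" in best.motif.tag
        built = merge_fragments(stems + loops)
        assert relaxed_recovery(built, crystal.model) >= 0.8
        # loop nucleotides pass the per-nucleotide correlation threshold
        assert all(np.isnan(f.rscc) or f.rscc > -1 for f in loops)

    def test_stage_isolation(self, helix_crystal, helix_map_good,
                             helix_phosphates):
        """Loop building never changes what the helix stage produced."""
        a = place_helices(helix_map_good, helix_phosphates, "A-RNA")
        b = place_helices(helix_map_good, helix_phosphates, "A-RNA")
        extend_with_loops(b, default_library(), helix_map_good,
                          helix_phosphates)
        assert len(a) == len(b)
        for fa, fb in zip(a, b):
            assert np.allclose(fa.model.xyz, fb.model.xyz)
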