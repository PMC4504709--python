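"""Contact maps, typed side-chain contacts, heptad counts, hydrogen bonds."""

import itertools
import warnings

import numpy as np
import pytest

from conftest import random_rotation
from ifdimer.contacts import (
    DEFAULT_CONTACT_TABLE, ContactTypeTable, HBondCriteria, HeptadRegister,
    aggregate_contact_probability, ca_contact_map, count_hbonds,
    detect_sidechain_contacts, ideal_ad_contacts, summarize_contacts,
)
from ifdimer.structure_io import ChainStructure, DimerStructure, Ensemble, Residue
from ifdimer.synthetic_data import (
    CrickParams, NoiseSpec, generate_crick_coil, perturb_ensemble,
)


def two_residue_dimer(distance):
    chains = [
        ChainStructure("K1", [Residue("ALA", 1, {"CA": np.zeros(3)})]),
        ChainStructure("K10", [Residue("ALA", 1, {"CA": np.array([distance, 0.0, 0.0])})]),
    ]
    return DimerStructure(chains)


def brute_force_pairs(frame, cutoff=12.0, exclusion=2):
    """Naive all-pairs oracle for the Cα contact map."""
    entries = []
    for chain in frame.chains:
        for res in chain.residues:
            entries.append((chain.label, res.number, res.ca))
    found = set()
    for (li, ni, pi), (lj, nj, pj) in itertools.combinations(entries, 2):
        if li == lj and abs(ni - nj) <= exclusion:
            continue
        if np.linalg.norm(pi - pj) < cutoff:
            found.add(((li, ni), (lj, nj)))
    return found


class TestCaContactMap:
    def test_just_below_cutoff_included(self):
        cmap = ca_contact_map(two_residue_dimer(11.9))
        assert (("K1", 1), ("K10", 1)) in cmap.pairs
        assert cmap.pairs[(("K1", 1), ("K10", 1))] == "K1-K10"

    def test_above_cutoff_excluded(self):
        assert len(ca_contact_map(two_residue_dimer(12.1))) == 0

    def test_exactly_at_cutoff_excluded(self):
        """The 12 Å bound is strict: a pair at exactly 12 Å is out."""
        assert len(ca_contact_map(two_residue_dimer(12.0))) == 0

    def test_sequence_exclusion(self):
        res = [Residue("GLY", i + 1, {"CA": np.array([2.0 * i, 0.0, 0.0])})
               for i in range(4)]
        frame = DimerStructure([ChainStructure("K1", res)])
        cmap = ca_contact_map(frame)
        assert (("K1", 1), ("K1", 2)) not in cmap.pairs
        assert (("K1", 1), ("K1", 3)) not in cmap.pairs
        assert (("K1", 1), ("K1", 4)) in cmap.pairs

    def test_matches_brute_force_oracle(self, reference_coil):
        cmap = ca_contact_map(reference_coil)
        assert set(cmap.pairs) == brute_force_pairs(reference_coil)

    def test_matches_oracle_on_jittered_frames(self, reference_coil):
        ens = perturb_ensemble(reference_coil, 3, NoiseSpec(1.0, seed=9))
        for frame in ens:
            assert set(ca_contact_map(frame).pairs) == brute_force_pairs(frame)

    def test_monotone_in_cutoff(self, reference_coil):
        sizes = [len(ca_contact_map(reference_coil, cutoff=c))
                 for c in (6.0, 9.0, 12.0, 15.0)]
        assert sizes == sorted(sizes)
        for small, large in ((6.0, 12.0), (9.0, 15.0)):
            a = set(ca_contact_map(reference_coil, cutoff=small).pairs)
            b = set(ca_contact_map(reference_coil, cutoff=large).pairs)
            assert a <= b


class TestAggregation:
    def _ensemble_with_presence(self, present_flags):
        """Frames where the single cross-chain pair is in contact iff the
        flag says so (11 Å vs 20 Å)."""
        frames = [two_residue_dimer(11.0 if f else 20.0) for f in present_flags]
        return Ensemble(frames)

    def test_always_present_probability_one(self):
        ens = self._ensemble_with_presence([True] * 5)
        maps = [ca_contact_map(f) for f in ens]
        m = aggregate_contact_probability(maps, ens)
        assert m.probabilities[(("K1", 1), ("K10", 1))] == 1.0

    def test_half_present(self):
        ens = self._ensemble_with_presence([True] * 10 + [False] * 10)
        maps = [ca_contact_map(f) for f in ens]
        m = aggregate_contact_probability(maps, ens, weighting="per-frame")
        assert m.probabilities[(("K1", 1), ("K10", 1))] == 0.5

    def test_truncated_models_excluded_from_denominator(self):
        """A tail-region pair present in every full model has probability
        1.0: the truncated (tail-less) models never enter its denominator."""
        def full_frame():
            chains = [
                ChainStructure("K1", [
                    Residue("ALA", 1, {"CA": np.zeros(3)}),
                    Residue("ALA", 400, {"CA": np.array([50.0, 0, 0])}),
                ]),
                ChainStructure("K10", [
                    Residue("ALA", 1, {"CA": np.array([0.0, 8.0, 0.0])}),
                    Residue("ALA", 380, {"CA": np.array([55.0, 0, 0])}),
                ]),
            ]
            return DimerStructure(chains)

        def truncated_frame():
            chains = [
                ChainStructure("K1", [Residue("ALA", 1, {"CA": np.zeros(3)})]),
                ChainStructure("K10", [Residue("ALA", 1, {"CA": np.array([0.0, 8.0, 0.0])})]),
            ]
            return DimerStructure(chains)

        frames = [full_frame() for _ in range(2)] + \
                 [truncated_frame() for _ in range(3)]
        ens = Ensemble(frames, model_ids=[0, 0, 1, 1, 1],
                       model_scopes=["full", "full", "truncated",
                                     "truncated", "truncated"])
        maps = [ca_contact_map(f) for f in ens]
        m = aggregate_contact_probability(maps, ens)
        tail_pair = (("K1", 400), ("K10", 380))
        assert m.probabilities[tail_pair] == 1.0

    def test_single_frame_values_binary(self, reference_coil):
        ens = Ensemble([reference_coil])
        maps = [ca_contact_map(reference_coil)]
        m = aggregate_contact_probability(maps, ens)
        assert set(m.probabilities.values()) <= {0.0, 1.0}
        assert all(0.0 <= p <= 1.0 for p in m.probabilities.values())

    def test_inconsistent_cutoffs_rejected(self, reference_coil):
        ens = Ensemble([reference_coil, reference_coil])
        maps = [ca_contact_map(reference_coil, cutoff=12.0),
                ca_contact_map(reference_coil, cutoff=10.0)]
        with pytest.raises(ValueError, match="cutoff"):
            aggregate_contact_probability(maps, ens)

    def test_jittered_frequencies_within_binomial_error(self):
        """A pair placed at the cutoff boundary under Gaussian jitter has a
        predictable contact frequency; the aggregated probability must sit
        within binomial sampling error of it.  At distance exactly 12 Å
        with isotropic jitter the one-axis crossing probability is ~0.5."""
        frames = 400
        ens = perturb_ensemble(two_residue_dimer(12.0), frames,
                               NoiseSpec(0.8, seed=21))
        maps = [ca_contact_map(f) for f in ens]
        m = aggregate_contact_probability(maps, ens, weighting="per-frame")
        p = m.probabilities.get((("K1", 1), ("K10", 1)), 0.0)
        # 5 sigma binomial band around 1/2
        assert abs(p - 0.5) < 5 * np.sqrt(0.25 / frames) + 0.02


def residue_with(name, number, atoms):
    return Residue(name, number, {k: np.asarray(v, float) for k, v in atoms.items()})


class TestSidechainContacts:
    def _frame(self, res_a, res_b):
        return DimerStructure([
            ChainStructure("K1", [res_a]),
            ChainStructure("K10", [res_b]),
        ])

    def test_acid_base_contact(self):
        glu = residue_with("GLU", 1, {"CA": [0, 0, 0], "OE1": [1, 0, 0],
                                      "OE2": [0.5, 1, 0]})
        lys = residue_with("LYS", 1, {"CA": [6, 0, 0], "NZ": [4.5, 0, 0]})
        found = detect_sidechain_contacts(self._frame(glu, lys))
        assert len(found) == 1
        assert found[0].interaction_class == "acid-base"
        assert found[0].distance == pytest.approx(3.5)  # closest site pair

    def test_aromatic_beyond_cutoff_excluded(self):
        """Phe/Phe ring centroids at cutoff + 0.1 Å: no contact."""
        ring = {"CG": [0, 1, 0], "CD1": [0.87, 0.5, 0], "CD2": [-0.87, 0.5, 0],
                "CE1": [0.87, -0.5, 0], "CE2": [-0.87, -0.5, 0], "CZ": [0, -1, 0]}
        f1 = residue_with("PHE", 1, {"CA": [0, 0, 0], **ring})
        sep = DEFAULT_CONTACT_TABLE.cutoffs["aromatic"] + 0.1
        ring2 = {k: [v[0] + sep, v[1], v[2]] for k, v in ring.items()}
        f2 = residue_with("PHE", 1, {"CA": [sep, 0, 0], **ring2})
        assert detect_sidechain_contacts(self._frame(f1, f2)) == []
        # and just inside the cutoff the same pair is aromatic
        ring3 = {k: [v[0] + sep - 0.2, v[1], v[2]] for k, v in ring.items()}
        f3 = residue_with("PHE", 1, {"CA": [sep - 0.2, 0, 0], **ring3})
        found = detect_sidechain_contacts(self._frame(f1, f3))
        assert [c.interaction_class for c in found] == ["aromatic"]

    def test_one_type_per_pair_precedence(self):
        """A Ser/Ser pair within both hydrogen-bond and hydrophobic range
        counts once, as the higher-precedence hydrogen bond."""
        s1 = residue_with("SER", 1, {"CA": [0, 0, 0], "CB": [1, 0, 0],
                                     "OG": [2, 0, 0]})
        s2 = residue_with("SER", 1, {"CA": [5, 0, 0], "CB": [4, 0, 0],
                                     "OG": [3.2, 0, 0]})
        found = detect_sidechain_contacts(self._frame(s1, s2))
        assert len(found) == 1
        assert found[0].interaction_class == "hydrogen-bond"

    def test_polar_double_site_check(self):
        """Gln/Asn pairs: both side-chain sites are tested — a contact
        through the second site alone still counts."""
        gln = residue_with("GLN", 1, {"CA": [0, 0, 0], "OE1": [20, 20, 20],
                                      "NE2": [1.0, 0, 0]})
        asn = residue_with("ASN", 1, {"CA": [5, 0, 0], "OD1": [4.0, 0, 0],
                                      "ND2": [25, 25, 25]})
        found = detect_sidechain_contacts(self._frame(gln, asn))
        assert len(found) == 1
        assert found[0].interaction_class == "hydrogen-bond"
        assert found[0].distance == pytest.approx(3.0)

    def test_missing_reference_atoms_skipped(self):
        bare_glu = residue_with("GLU", 1, {"CA": [0, 0, 0]})
        lys = residue_with("LYS", 1, {"CA": [4, 0, 0], "NZ": [2, 0, 0]})
        assert detect_sidechain_contacts(self._frame(bare_glu, lys)) == []

    def test_census_rigid_invariance_and_chain_swap(self, rng):
        glu = residue_with("GLU", 1, {"CA": [0, 0, 0], "OE1": [1, 0, 0]})
        lys = residue_with("LYS", 1, {"CA": [6, 0, 0], "NZ": [4.0, 0, 0]})
        frame = self._frame(glu, lys)
        R = random_rotation(rng)
        moved = frame.transformed(R, np.array([7.0, -2.0, 1.0]))
        c1 = detect_sidechain_contacts(frame)
        c2 = detect_sidechain_contacts(moved)
        assert [(c.interaction_class, round(c.distance, 6)) for c in c1] == \
               [(c.interaction_class, round(c.distance, 6)) for c in c2]
        # swapping chain labels only relabels the chain class
        swapped = DimerStructure([
            ChainStructure("K10", [glu]), ChainStructure("K1", [lys])])
        c3 = detect_sidechain_contacts(swapped)
        assert c3[0].chain_class == "K1-K10" == c1[0].chain_class
        assert c3[0].interaction_class == c1[0].interaction_class


class TestSummary:
    def _frame_with_contacts(self, n):
        """n disjoint Glu-Lys acid-base pairs, 30 Å apart from each other."""
        k1, k10 = [], []
        for i in range(n):
            off = 30.0 * i
            k1.append(residue_with("GLU", i + 1,
                                   {"CA": [off, 0, 0], "OE1": [off + 1, 0, 0]}))
            k10.append(residue_with("LYS", i + 1,
                                    {"CA": [off + 5, 0, 0], "NZ": [off + 4, 0, 0]}))
        return DimerStructure([ChainStructure("K1", k1),
                               ChainStructure("K10", k10)])

    def test_single_frame_totals(self):
        ens = Ensemble([self._frame_with_contacts(3)])
        s = summarize_contacts(ens)
        assert s.total == pytest.approx(3.0)

    def test_mean_over_disjoint_frames(self):
        """Frames with disjoint contact sets of sizes 2 and 4 average to a
        mean simultaneous-contact count of 3."""
        f2 = self._frame_with_contacts(2)
        f4 = self._frame_with_contacts(4)
        # displace f4 so its pairs are disjoint from f2's in residue space
        k1 = [residue_with("GLU", i + 10, dict(zip(("CA", "OE1"),
              [r.atoms["CA"], r.atoms["OE1"]]))) for i, r in enumerate(f4.chain("K1").residues)]
        k10 = [residue_with("LYS", i + 10, dict(zip(("CA", "NZ"),
               [r.atoms["CA"], r.atoms["NZ"]]))) for i, r in enumerate(f4.chain("K10").residues)]
        f4 = DimerStructure([ChainStructure("K1", k1), ChainStructure("K10", k10)])
        ens = Ensemble([f2, f4], model_ids=[0, 1])
        s = summarize_contacts(ens)
        assert s.total == pytest.approx(3.0)
        assert set(s.pair_probabilities["probability"]) == {0.5}

    def test_known_jitter_frequencies(self, reference_coil):
        """Summed probabilities from a seeded jitter ensemble agree with an
        independent per-frame recount within binomial error."""
        ens = perturb_ensemble(reference_coil, 20, NoiseSpec(0.3, seed=13))
        s = summarize_contacts(ens)
        manual = np.mean([len(detect_sidechain_contacts(f)) for f in ens])
        assert s.total == pytest.approx(manual, abs=1e-9)


class TestHeptadRegister:
    def test_single_heptad_hand_count(self):
        """Two aligned heptads (a…g): a and d each pair once per chain → 4
        knob interactions, matching manual enumeration of the rule."""
        reg = HeptadRegister.from_segments([
            ("K1", 1, 7, "a"), ("K10", 1, 7, "a"),
        ])
        assert ideal_ad_contacts(reg, "K1", (1, 7), "K10", (1, 7)) == 4

    def test_empty_range(self):
        reg = HeptadRegister.from_segments([("K1", 1, 7, "a"), ("K10", 1, 7, "a")])
        assert ideal_ad_contacts(reg, "K1", (1, 0), "K10", (1, 0)) == 0

    def test_multi_heptad_scaling(self):
        reg = HeptadRegister.from_segments([
            ("K1", 1, 70, "a"), ("K10", 1, 70, "a"),
        ])
        # 10 heptads, 4 per heptad
        assert ideal_ad_contacts(reg, "K1", (1, 70), "K10", (1, 70)) == 40

    def test_stutter_equals_brute_force(self):
        """A register with one stutter discontinuity: production count
        equals direct enumeration over the discontinuous letters."""
        reg = HeptadRegister.from_segments([
            ("K1", 1, 21, "a"), ("K1", 22, 42, "d"),
            ("K10", 1, 21, "a"), ("K10", 22, 42, "d"),
        ])
        span = 42
        expected = 0
        for cx, cy in (("K1", "K10"), ("K10", "K1")):
            for rel in range(span):
                lx = reg.letter(cx, 1 + rel)
                if lx == "a" and rel + 3 < span and reg.letter(cy, 1 + rel + 3) == "d":
                    expected += 1
                elif lx == "d" and rel - 3 >= 0 and reg.letter(cy, 1 + rel - 3) == "a":
                    expected += 1
        assert ideal_ad_contacts(reg, "K1", (1, 42), "K10", (1, 42)) == expected

    def test_unassigned_register_rejected(self):
        reg = HeptadRegister.from_segments([("K1", 1, 7, "a")])
        with pytest.raises(ValueError, match="unassigned"):
            ideal_ad_contacts(reg, "K1", (1, 7), "K10", (1, 7))


class TestHBonds:
    def _frame(self, *residues_per_chain):
        chains = [ChainStructure(lab, res)
                  for lab, res in zip(("K1", "K10"), residues_per_chain)]
        return DimerStructure(chains)

    def test_close_pair_counted(self):
        a = residue_with("SER", 1, {"CA": [0, 0, 0], "OG": [1, 0, 0]})
        b = residue_with("SER", 1, {"CA": [5, 0, 0], "OG": [3.9, 0, 0]})
        counts = count_hbonds(self._frame([a], [b]))
        assert counts["sidechain-sidechain"] == 1

    def test_beyond_distance_not_counted(self):
        a = residue_with("SER", 1, {"CA": [0, 0, 0], "OG": [1, 0, 0]})
        b = residue_with("SER", 1, {"CA": [6, 0, 0], "OG": [4.6, 0, 0]})
        counts = count_hbonds(self._frame([a], [b]))
        assert sum(counts.values()) == 0

    def test_ideal_helix_i_to_i4_count(self):
        """A 20-residue ideal α-helix has exactly the 16 i→i+4 backbone
        hydrogen bonds under the default geometric criteria."""
        from ifdimer.model_builder import DihedralSpec, chain_from_dihedrals
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            helix = chain_from_dihedrals(
                "A" * 20, DihedralSpec.uniform(20, -57.0, -47.0, 180.0))
        counts = count_hbonds(DimerStructure([helix]))
        assert counts["backbone-backbone"] == 16
        assert counts["backbone-sidechain"] == 0
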