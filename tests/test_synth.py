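"""Generator closure: planted parameters are recovered by the matching
analysis stage, and outputs are deterministic under a fixed seed."""

import math

import numpy as np
import pytest

from evorate.codon import estimate_pair
from evorate.composition import composition, correlate_composition
from evorate.domains import build_consensus, deviation_counts
from evorate.errors import EvorateError, ZeroVarianceError
from evorate.association import fit_association
from evorate.io import SpeciesTraits, TraitTable
from evorate.median import GeneSpeciesCharacteristic
from evorate.synth import (
    GeneSpec,
    LqModel,
    PlannedDeviation,
    StudyConfig,
    TraitModel,
    generate_composition_profiles,
    generate_domain_alignment,
    generate_ortholog_set,
    generate_traits,
    noise_sd_for_target_r,
    profile_to_sequence,
)


class TestOrthologSet:
    def test_deterministic(self):
        cfg = StudyConfig(n_species=8, n_codons=40, seed=3)
        a1, m1 = generate_ortholog_set(cfg)
        a2, m2 = generate_ortholog_set(cfg)
        assert a1 == a2 and m1 == m2

    def test_constant_omega_estimates_cluster(self):
        cfg = StudyConfig(
            n_species=10,
            n_codons=800,
            genes=(GeneSpec("g", omega_mode="constant", omega=0.05),),
            t=0.4,
            seed=11,
        )
        alns, omap = generate_ortholog_set(cfg)
        aln = alns["g"]
        omegas = []
        for i, (_, sa) in enumerate(aln.entries):
            for _, sb in aln.entries[i + 1:]:
                om = estimate_pair(sa, sb).omega
                if om is not None:
                    omegas.append(om)
        assert 0.0 < np.median(omegas) < 0.15  # clusters near 0.05

    def test_pseudogene_fraction_and_internal_stops(self):
        cfg = StudyConfig(
            n_species=10,
            n_codons=40,
            genes=(GeneSpec("g", pseudogene_fraction=0.2),),
            seed=5,
        )
        alns, omap = generate_ortholog_set(cfg)
        pseudo = [r for r in omap.records if r.status == "pseudogene"]
        assert len(pseudo) == math.ceil(0.2 * 10)
        from Bio.Seq import Seq

        for r in pseudo:
            prot = str(Seq(alns["g"].sequence(r.species_id)).translate())
            assert "*" in prot[:-1]

    def test_lost_species_absent_from_alignment(self):
        cfg = StudyConfig(
            n_species=10,
            n_codons=30,
            genes=(GeneSpec("g", lost_fraction=0.2),),
            seed=6,
        )
        alns, omap = generate_ortholog_set(cfg)
        lost = {r.species_id for r in omap.records if r.status == "lost"}
        assert len(lost) == 2
        assert lost.isdisjoint(alns["g"].species)


class TestTraits:
    def _chars(self, medians):
        return [
            GeneSpeciesCharacteristic("g", sp, "t", m, 3, 0)
            for sp, m in medians.items()
        ]

    def test_zero_noise_exact_recovery(self):
        medians = {f"sp{i}": 0.09 + 0.005 * i for i in range(15)}
        model = TraitModel(mrls_noise_sd=0.0, lg_weight_noise_sd=0.0)
        traits = generate_traits(medians, model, seed=1)
        res = fit_association(self._chars(medians), traits, "mrls")
        assert res.slope == pytest.approx(439, rel=1e-9)
        assert res.intercept == pytest.approx(-36, rel=1e-9)
        assert res.r == pytest.approx(1.0)
        res_w = fit_association(self._chars(medians), traits, "lg_weight")
        assert res_w.slope == pytest.approx(25, rel=1e-6)

    def test_equal_medians_raise_zero_variance_downstream(self):
        medians = {f"sp{i}": 0.1 for i in range(10)}
        traits = generate_traits(medians, TraitModel(), seed=2)
        with pytest.raises(ZeroVarianceError):
            fit_association(self._chars(medians), traits, "mrls")

    def test_deterministic(self):
        medians = {f"sp{i}": 0.09 + 0.01 * i for i in range(8)}
        t1 = generate_traits(medians, TraitModel(), seed=9, lq_model=LqModel(),
                             lq_carriers={"sp1"})
        t2 = generate_traits(medians, TraitModel(), seed=9, lq_model=LqModel(),
                             lq_carriers={"sp1"})
        assert list(t1) == list(t2)

    def test_lq_carrier_shift_direction(self):
        medians = {f"sp{i}": 0.1 + 0.001 * i for i in range(400)}
        carriers = {f"sp{i}" for i in range(200)}
        traits = generate_traits(
            medians, TraitModel(), seed=3,
            lq_model=LqModel(planted_percent_difference=17.0),
            lq_carriers=carriers,
        )
        lq_in = np.median([t.lq for t in traits if t.species_id in carriers])
        lq_out = np.median([t.lq for t in traits if t.species_id not in carriers])
        assert lq_in > lq_out

    def test_noise_calibration_formula(self):
        # r = signal/sqrt(signal^2+noise^2) inverted
        sd = noise_sd_for_target_r(439, 0.03, 0.76)
        signal = 439 * 0.03
        assert signal / math.hypot(signal, sd) == pytest.approx(0.76)


class TestCompositionProfiles:
    def test_profiles_sum_to_100(self):
        tv = {f"sp{i}": 10.0 + i for i in range(20)}
        profs = generate_composition_profiles(tv, {"L": 0.62, "P": -0.7}, seed=4)
        for p in profs:
            assert sum(p.occurrence.values()) == pytest.approx(100.0)

    def test_planted_signs_recovered(self):
        tv = {f"sp{i}": 10.0 + 1.5 * i for i in range(60)}
        profs = generate_composition_profiles(tv, {"L": 0.62, "P": -0.7}, seed=5)
        traits = TraitTable([SpeciesTraits(sp, mrls=v) for sp, v in tv.items()])
        out = correlate_composition(profs, traits, "mrls")
        assert out["L"].r > 0.3
        assert out["P"].r < -0.4

    def test_sequence_realisation_recovers_profile(self):
        tv = {f"sp{i}": 10.0 + i for i in range(5)}
        prof = generate_composition_profiles(tv, {"L": 0.5}, seed=6)[0]
        seq = profile_to_sequence(prof, length=100000)
        back = composition(seq, prof.species_id)
        for aa in back.occurrence:
            assert back.occurrence[aa] == pytest.approx(
                prof.occurrence[aa], abs=0.001
            )

    def test_slack_cannot_be_planted(self):
        with pytest.raises(ValueError):
            generate_composition_profiles(
                {"a": 1.0, "b": 2.0, "c": 3.0}, {"G": 0.5}, seed=1
            )


class TestDomainGenerator:
    def test_empty_plan_no_deviations(self):
        aln, tmap, cons = generate_domain_alignment({"t1": 5, "t2": 4}, seed=1)
        table = deviation_counts(aln, cons, tmap)
        assert all(c == 0 for t in table.taxa for c in table.counts[t])
        assert table.conservative_positions["overall"] == 54

    def test_plan_recovered_exactly(self):
        plan = (
            PlannedDeviation(19, "t1", 5, radical=True),
            PlannedDeviation(3, "t2", 2, radical=True),
        )
        aln, tmap, cons = generate_domain_alignment({"t1": 9, "t2": 6}, plan, seed=2)
        rad = deviation_counts(aln, cons, tmap, "radical")
        assert rad.counts["t1"][18] == 5
        assert rad.counts["t2"][2] == 2
        assert sum(rad.counts["t1"]) == 5

    def test_conservative_plan_counts_in_all_mode_only(self):
        plan = (PlannedDeviation(7, "t1", 3, radical=False),)
        aln, tmap, cons = generate_domain_alignment({"t1": 6}, plan, seed=3)
        allc = deviation_counts(aln, cons, tmap, "all")
        radc = deviation_counts(aln, cons, tmap, "radical")
        assert allc.counts["t1"][6] == 3
        assert radc.counts["t1"][6] == 0

    def test_consensus_rebuilt_from_alignment(self):
        plan = (PlannedDeviation(19, "t1", 2),)
        aln, tmap, cons = generate_domain_alignment({"t1": 8}, plan, seed=4)
        rebuilt, _ = build_consensus(aln)
        assert rebuilt == cons

    def test_overfull_plan_rejected(self):
        with pytest.raises(EvorateError):
            generate_domain_alignment(
                {"t1": 3}, (PlannedDeviation(1, "t1", 4),), seed=5
            )

    def test_deterministic(self):
        plan = (PlannedDeviation(10, "t1", 2),)
        a = generate_domain_alignment({"t1": 5}, plan, seed=6)
        b = generate_domain_alignment({"t1": 5}, plan, seed=6)
        assert a == b
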