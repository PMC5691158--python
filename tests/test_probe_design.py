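"""Probe-design unit and property tests.

Independent oracles: brute-force substring scans for adapter absence and arm
uniqueness, an independent nearest-neighbor Tm implementation, and explicit
reverse-complement k-mer scans for the self-complementarity screen.
"""

import itertools
import math

import numpy as np
import pytest

from catd.probe_design import (
    Adapter,
    DesignError,
    PadlockProbe,
    ProbeLibrary,
    TargetDeletion,
    TargetSNP,
    TmParams,
    design_adapter,
    design_catd_probe_set,
    design_kebab_tiling,
    design_snp_probe,
    design_snp_probes,
    melting_temperature,
    reverse_complement,
    self_complementarity_screen,
)

from conftest import random_dna, revcomp

TM = TmParams()


# ---------------------------------------------------------------------------
# Independent Tm oracle: unified nearest-neighbor tables, written from the
# published parameter set, sharing no code with the implementation.
# ---------------------------------------------------------------------------

_NN_DH_DS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_R = 1.987  # cal / (mol K)


def tm_oracle(seq: str, na_mM: float = 50.0, oligo_nM: float = 250.0) -> float:
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        init = _INIT_GC if end in "GC" else _INIT_AT
        dh += init[0]
        ds += init[1]
    for a, b in zip(seq, seq[1:]):
        pair_dh, pair_ds = _NN_DH_DS[a + b]
        dh += pair_dh
        ds += pair_ds
    # monovalent-salt entropy correction
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    # non-self-complementary duplex, equal strand concentrations: the excess
    # single-strand concentration entering the van't Hoff term is half of one
    # strand's concentration
    c_t = oligo_nM * 1e-9 / 2.0
    return dh * 1000.0 / (ds + _R * math.log(c_t)) - 273.15


def count_occurrences_brute(hay: str, needle: str) -> int:
    return sum(
        1 for i in range(len(hay) - len(needle) + 1)
        if hay[i:i + len(needle)] == needle
    )


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------


class TestMeltingTemperature:
    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")
        with pytest.raises(ValueError):
            melting_temperature("")

    def test_non_acgt_raises(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTACGTACGTACG")

    def test_deterministic(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert melting_temperature(seq) == melting_temperature(seq)

    def test_matches_independent_nearest_neighbor_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            seq = random_dna(rng, int(rng.integers(15, 36)))
            assert melting_temperature(seq, TM) == pytest.approx(
                tm_oracle(seq), abs=0.5
            )

    def test_gc_extension_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            seq = random_dna(rng, 20)
            assert melting_temperature(seq + "GC", TM) >= melting_temperature(
                seq, TM
            )


# ---------------------------------------------------------------------------
# Adapter design
# ---------------------------------------------------------------------------


class TestDesignAdapter:
    def test_absent_and_deterministic(self):
        reference = {"r": "ACGT" * 25}
        a1 = design_adapter(reference, length=20, rng_seed=1)
        a2 = design_adapter(reference, length=20, rng_seed=1)
        assert a1.sequence == a2.sequence
        assert len(a1.sequence) == 20
        assert count_occurrences_brute(reference["r"], a1.sequence) == 0
        assert count_occurrences_brute(reference["r"], revcomp(a1.sequence)) == 0

    def test_below_minimum_length(self):
        with pytest.raises(DesignError):
            design_adapter({"r": "ACGT" * 25}, length=19, rng_seed=1)

    def test_succeeds_on_all_10mers_reference(self):
        # every 10-mer occurs, but 20-mers are nowhere near exhausted
        all_10mers = "".join(
            "".join(kmer) for kmer in itertools.product("ACGT", repeat=10)
        )
        reference = {"dense": all_10mers}
        adapter = design_adapter(reference, length=20, rng_seed=3)
        assert adapter.sequence not in all_10mers
        assert revcomp(adapter.sequence) not in all_10mers

    def test_composition_constraints(self):
        adapter = design_adapter({"r": "ACGT" * 25}, length=28, rng_seed=9)
        gc = sum(b in "GC" for b in adapter.sequence) / 28
        assert 0.4 <= gc <= 0.6
        assert max(
            len(list(g)) for _, g in itertools.groupby(adapter.sequence)
        ) <= 4

    def test_adapter_type_enforces_minimum(self):
        with pytest.raises(ValueError):
            Adapter(name="x", sequence="ACGTACGTACG")


# ---------------------------------------------------------------------------
# Cat-D probes
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def catd_inputs():
    rng = np.random.default_rng(21)
    context = random_dna(rng, 150)
    adapter = design_adapter(
        {"ctx": context}, length=28, rng_seed=4, name="ad", tm_params=TM
    )
    return adapter, context


class TestDesignCatd:
    def test_five_distinct_probes(self, catd_inputs):
        adapter, context = catd_inputs
        probes = design_catd_probe_set(adapter, context, 5, TM, target="delX")
        assert len(probes) == 5
        assert len({p.name for p in probes}) == 5
        assert len({p.arm_start for p in probes}) == 5

    def test_zero_probes(self, catd_inputs):
        adapter, context = catd_inputs
        assert design_catd_probe_set(adapter, context, 0, TM) == []

    def test_arm_constraints(self, catd_inputs):
        adapter, context = catd_inputs
        for p in design_catd_probe_set(adapter, context, 5, TM):
            assert len(p.extension_arm) >= 20
            assert len(p.ligation_arm) >= 20
            assert abs(melting_temperature(p.ligation_arm, TM) - 55) <= 3

    def test_extension_arm_is_rc_of_adapter_suffix(self, catd_inputs):
        adapter, context = catd_inputs
        for p in design_catd_probe_set(adapter, context, 5, TM):
            suffix = adapter.sequence[-len(p.extension_arm):]
            assert p.extension_arm == revcomp(suffix)

    def test_ligation_offset_bounded(self, catd_inputs):
        adapter, context = catd_inputs
        junction = len(context)
        for p in design_catd_probe_set(adapter, context, 5, TM,
                                       max_lig_offset=30):
            offset = junction - p.capture_interval[0]
            assert 0 <= offset <= 30

    def test_context_too_short(self, catd_inputs):
        adapter, _ = catd_inputs
        with pytest.raises(DesignError):
            design_catd_probe_set(adapter, "ACGT" * 20, 5, TM)


# ---------------------------------------------------------------------------
# Kebab tiling
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def kebab_reference():
    rng = np.random.default_rng(33)
    return {"chr1": random_dna(rng, 100_000)}


class TestKebabTiling:
    def test_containment_single_probe(self, kebab_reference):
        deletion = TargetDeletion("d", "chr1", 30_000, 60_000, (40_000, 50_000))
        (probe,) = design_kebab_tiling(deletion, kebab_reference, 1, TM)
        g0, g1 = probe.capture_interval
        assert 40_000 <= g0 < g1 <= 50_000

    def test_tiling_disjoint_and_contained(self, kebab_reference):
        deletion = TargetDeletion("d", "chr1", 30_000, 60_000, (35_000, 55_000))
        probes = design_kebab_tiling(deletion, kebab_reference, 10, TM)
        assert len(probes) == 10
        intervals = sorted(p.capture_interval for p in probes)
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            assert a1 <= b0
        for g0, g1 in intervals:
            assert 35_000 <= g0 < g1 <= 55_000

    def test_arm_uniqueness_brute_force(self, kebab_reference):
        deletion = TargetDeletion("d", "chr1", 30_000, 60_000, (40_000, 50_000))
        hay = kebab_reference["chr1"]
        hay_rc = revcomp(hay)
        for p in design_kebab_tiling(deletion, kebab_reference, 3, TM):
            for arm in (p.extension_arm, p.ligation_arm):
                assert (
                    count_occurrences_brute(hay, arm)
                    + count_occurrences_brute(hay_rc, arm)
                ) == 1

    def test_interval_too_small(self, kebab_reference):
        deletion = TargetDeletion("d", "chr1", 30_000, 60_000, (40_000, 40_500))
        with pytest.raises(DesignError):
            design_kebab_tiling(deletion, kebab_reference, 10, TM)


# ---------------------------------------------------------------------------
# SNP probes
# ---------------------------------------------------------------------------


class TestSnpProbes:
    def test_capture_contains_variant(self, kebab_reference):
        pos = 70_000
        ref = kebab_reference["chr1"][pos]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        snp = TargetSNP("s1", "chr1", pos, ref, alt)
        probe = design_snp_probe(snp, kebab_reference, TM)
        g0, g1 = probe.capture_interval
        assert g0 < pos < g1
        read_pos = len(probe.ligation_arm) + (pos - g0) + 1
        assert 21 <= read_pos <= 67

    def test_two_close_variants_share_one_probe(self, kebab_reference):
        seq = kebab_reference["chr1"]

        def mk(name, pos):
            ref = seq[pos]
            return TargetSNP(name, "chr1", pos, ref,
                             "ACGT"[("ACGT".index(ref) + 1) % 4])

        snps = [mk("a", 70_000), mk("b", 70_005), mk("c", 75_000)]
        probes = design_snp_probes(snps, kebab_reference, TM)
        assert len(probes) == 2
        shared = next(p for p in probes if len(p.targets) == 2)
        assert set(shared.targets) == {"a", "b"}

    def test_flank_too_short(self):
        snp = TargetSNP("s", "c", 50, "A", "T")
        with pytest.raises(DesignError):
            design_snp_probe(snp, {"c": "A" * 200}, TM)

    def test_ref_allele_mismatch(self, kebab_reference):
        pos = 70_000
        ref = kebab_reference["chr1"][pos]
        wrong = "ACGT"[("ACGT".index(ref) + 1) % 4]
        snp = TargetSNP("s", "chr1", pos, wrong, ref)
        with pytest.raises(DesignError):
            design_snp_probe(snp, kebab_reference, TM)


# ---------------------------------------------------------------------------
# Self-complementarity screen
# ---------------------------------------------------------------------------


def _probe_with(ext, lig, linker):
    return PadlockProbe(
        name="p", kind="kebab", extension_arm=ext, ligation_arm=lig,
        linker=linker, target="t", chrom="c",
        arm_start=0, capture_interval=(len(lig), len(lig)),
        arm_end=len(lig) + len(ext),
    )


class TestSelfComplementarityScreen:
    LINKER = "TTCAGACGTGTGCTCTTCCGATCTGGAACG"

    def test_arm_vs_arm_rc_fails(self):
        lig = "ATCGGATTACAGCTTACGCA"
        probe = _probe_with(revcomp(lig), lig, self.LINKER)
        assert self_complementarity_screen(probe, max_hairpin_stem=7) is False

    def test_clean_probe_passes(self):
        # verified by brute scan below: no shared RC 8-mers between segments
        ext = "AAAAAAAACCCCAAAAAAAA"
        lig = "AAAACCCCAAAACCCCAAAA"
        linker = "CACACACACACACACACACA"
        segments = [ext, lig, linker]
        for a, b in itertools.combinations(segments, 2):
            for i in range(len(a) - 7):
                assert revcomp(a[i:i + 8]) not in b
        probe = _probe_with(ext, lig, linker)
        assert self_complementarity_screen(probe, max_hairpin_stem=7) is True

    def test_linker_rc_10mer_fails_at_stem_9(self):
        linker = self.LINKER
        ext = revcomp(linker[5:15]) + "AAAAACCCCC"
        probe = _probe_with(ext, "AAAACCCCAAAACCCCAAAA", linker)
        assert self_complementarity_screen(probe, max_hairpin_stem=9) is False
        # the same hit is tolerated once the stem allowance exceeds it
        assert self_complementarity_screen(probe, max_hairpin_stem=10) is True


# ---------------------------------------------------------------------------
# Library-level invariants
# ---------------------------------------------------------------------------


class TestLibraryInvariants:
    def test_every_probe_satisfies_arm_constraints(self, default_design):
        tm = TmParams()
        for p in default_design.library.probes:
            assert len(p.extension_arm) >= 20
            assert len(p.ligation_arm) >= 20
            assert abs(melting_temperature(p.ligation_arm, tm) - 55) <= 3
            assert abs(melting_temperature(p.extension_arm, tm) - 55) <= 3

    def test_adapters_absent_from_genome(self, default_design):
        genome = default_design.genome["chrS"]
        for adapter in default_design.library.adapters:
            assert count_occurrences_brute(genome, adapter.sequence) == 0
            assert count_occurrences_brute(genome, revcomp(adapter.sequence)) == 0

    def test_kebab_intervals_within_shared_region_and_disjoint(
        self, default_design
    ):
        c0, c1 = default_design.kebab_target.commonly_deleted
        intervals = sorted(
            p.capture_interval
            for p in default_design.library.by_kind("kebab")
        )
        for g0, g1 in intervals:
            assert c0 <= g0 < g1 <= c1
        for (_, a1), (b0, _) in zip(intervals, intervals[1:]):
            assert a1 <= b0

    def test_duplicate_probe_names_rejected(self, default_design):
        probes = default_design.library.probes
        with pytest.raises(ValueError, match="duplicate"):
            ProbeLibrary(probes=probes + [probes[0]],
                         adapters=default_design.library.adapters)

    def test_catd_probe_requires_known_adapter(self, default_design):
        catd = default_design.library.by_kind("catd")
        with pytest.raises(ValueError, match="adapter"):
            ProbeLibrary(probes=catd, adapters=[])

    def test_design_deterministic_in_seed(self, default_design):
        from catd.simulator import SimConfig, simulate_reference_and_library

        again = simulate_reference_and_library(SimConfig(seed=11))
        assert again.genome == default_design.genome
        assert again.library.probes == default_design.library.probes
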