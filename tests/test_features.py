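import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from premirna.core import SequenceRecord
from premirna.features import (
    FeatureError,
    FeatureSpec,
    NEW_FEATURES,
    TIER_A,
    base_features,
    dinucleotide_shuffle,
    dust_fraction,
    extract,
    loops_feature,
    orf_feature,
    read_feature_tsv,
    triplet_features,
    write_feature_tsv,
)
from premirna.folding import FoldResult, get_backend, parse_structure

rna_seq = st.text(alphabet="ACGU", min_size=10, max_size=80)


class TestTriplets:
    def test_all_paired_poly_a(self):
        assert triplet_features("AAAA", "((((") == (1.0, 0.0, 0.0, 0.0)

    def test_unpaired_structure_all_zero(self):
        assert triplet_features("GCGC", "....") == (0.0, 0.0, 0.0, 0.0)

    def test_mixed_brackets_no_window(self):
        # after ')'->'(' mapping no interior window is "((("
        assert triplet_features("GCGC", "(..)") == (0.0, 0.0, 0.0, 0.0)

    def test_closing_brackets_count_as_paired(self):
        # ")))" maps to "(((" so the middle G is counted
        assert triplet_features("AGA", ")))") == (0.0, 0.0, 1.0, 0.0)

    def test_length_errors(self):
        with pytest.raises(FeatureError):
            triplet_features("AC", "..")
        with pytest.raises(FeatureError):
            triplet_features("ACGU", "...")

    @given(rna_seq)
    def test_sum_bounded(self, seq):
        fr = get_backend("nussinov").fold(seq)
        vals = triplet_features(seq, fr.structure)
        assert sum(vals) <= 1.0 + 1e-12


class TestOrf:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AUGAAAUGA", 2), ("UAAUAAUAA", 2), ("AC", 0), ("UAAUAA", 1)],
    )
    def test_examples(self, seq, expected):
        assert orf_feature(seq) == expected

    @given(rna_seq)
    def test_bounded_by_codon_count(self, seq):
        assert 0 <= orf_feature(seq) <= len(seq) // 3


class TestLoops:
    @pytest.mark.parametrize(
        "structure,expected",
        [("((((...))))", 0), ("((..((...))))", 2), ("((..((...))..))", 4)],
    )
    def test_examples(self, structure, expected):
        fr = FoldResult(
            seq="A" * len(structure), structure=structure,
            mfe=-float(structure.count("(")),
        )
        assert loops_feature(parse_structure(fr)) == expected


class TestDust:
    def test_homopolymer_fully_masked(self):
        assert dust_fraction("A" * 64) == 100.0

    def test_triplet_diverse_sequence_unmasked(self):
        # cycles through many distinct triplets: nothing repeats enough
        seq = ("AUCG" "AACC" "GGUU" "ACGU" "AGCU" "UGCA" "CAGU" "GAUC"
               "AAGG" "CCUU" "AGGC" "UUAC" "GCAA" "UCCG" "GUAG" "CUAU")
        assert len(seq) == 64
        assert dust_fraction(seq) == 0.0

    def test_u_t_invariance(self):
        s = "GCGCGCGCGCAUAUAUAUAUACGGC"
        assert dust_fraction(s) == dust_fraction(s.replace("U", "T"))

    def test_monotone_under_masked_block_concatenation(self, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGU"), 50))
            before = dust_fraction(seq) * len(seq)
            longer = seq + "A" * 64
            after = dust_fraction(longer) * len(longer)
            assert after >= before - 1e-6

    def test_matches_dustmasker_oracle(self, tmp_path, rng):
        """Independent oracle: NCBI dustmasker at level 15 on mixed inputs."""
        seqs = {
            "homopoly": "A" * 64,
            "direpeat": "AU" * 40,
            "random": "".join(rng.choice(list("ACGU"), 100)),
            "embedded": "".join(rng.choice(list("ACGU"), 40))
            + "A" * 30
            + "".join(rng.choice(list("ACGU"), 40)),
        }
        fa = tmp_path / "in.fa"
        fa.write_text(
            "".join(f">{k}\n{v.replace('U', 'T')}\n" for k, v in seqs.items())
        )
        exe = shutil.which("dustmasker")
        assert exe, "dustmasker expected on PATH in the test environment"
        res = subprocess.run(
            [exe, "-in", str(fa), "-level", "15", "-outfmt", "acclist"],
            check=True, capture_output=True, text=True,
        )
        masked = {k: 0 for k in seqs}
        for line in res.stdout.splitlines():
            name, start, end = line.lstrip(">").split("\t")
            masked[name] += int(end) - int(start) + 1
        for k, v in seqs.items():
            expected = 100.0 * masked[k] / len(v)
            assert dust_fraction(v) == pytest.approx(expected, abs=1e-9), k


class TestDinucleotideShuffle:
    @given(st.text(alphabet="ACGU", min_size=4, max_size=60))
    def test_preserves_dinucleotide_counts(self, seq):
        rng = np.random.default_rng(0)
        sh = dinucleotide_shuffle(seq, rng)  # internal assertion re-checks
        assert sorted(sh) == sorted(seq)
        assert sh[0] == seq[0] and sh[-1] == seq[-1]

    def test_shuffles_actually_move(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 60))
        outs = {dinucleotide_shuffle(seq, rng) for _ in range(20)}
        assert len(outs) > 1


class TestBaseFeatures:
    def test_degenerate_homopolymer(self, nussinov):
        fr = nussinov.fold("A" * 20)
        vals = base_features("A" * 20, fr, nussinov)
        assert vals["dg"] == 0.0
        assert vals["dp"] == 0.0
        for name in ("mfei1", "mfei2", "mfei4", "avg_bp_per_stem"):
            assert vals[name] == 0.0

    def test_pure_gc_hairpin(self, nussinov):
        seq = "G" * 20 + "AAAA" + "C" * 20
        fr = nussinov.fold(seq)
        vals = base_features(seq, fr, nussinov)
        assert vals["dp"] == pytest.approx(20 / 44)
        assert vals["gc_per_len"] == pytest.approx(20 / 44)
        assert vals["au_per_len"] == 0.0

    def test_tier_b_needs_partition_function(self, nussinov):
        fr = nussinov.fold("GGGGGAAAACCCCC")
        with pytest.raises(Exception, match="tier B"):
            base_features("GGGGGAAAACCCCC", fr, nussinov, tiers="AB")

    def test_tier_b_values_finite(self, vienna):
        seq = "G" * 15 + "AAAA" + "C" * 15
        fr = vienna.fold(seq)
        vals = base_features(seq, fr, vienna, tiers="AB")
        assert 0.0 < vals["mfe_structure_freq"] <= 1.0
        assert all(math.isfinite(v) for v in vals.values())

    def test_tier_c_zero_sd_rule(self, nussinov):
        # a homopolymer is its own dinucleotide-shuffle fixed point:
        # sd of the shuffled statistics is 0 and the z-scores collapse to 0
        seq = "A" * 20
        fr = nussinov.fold(seq)
        vals = base_features(
            seq, fr, nussinov, tiers="AC", rng=np.random.default_rng(1),
            n_shuffle=5,
        )
        assert vals["z_dg"] == 0.0
        assert vals["z_dp"] == 0.0

    def test_tier_c_z_score_negative_for_stable_hairpin(self, vienna):
        # a perfect stem is thermodynamically far more stable than its
        # dinucleotide shuffles
        from premirna.fixtures import HairpinConfig, make_hairpin

        seq = make_hairpin(HairpinConfig(stem_len=18, loop_len=5, seed=9)).seq
        fr = vienna.fold(seq)
        vals = base_features(
            seq, fr, vienna, tiers="AC", rng=np.random.default_rng(2),
            n_shuffle=25,
        )
        assert vals["z_dg"] < -1.0


class TestExtract:
    def test_arity_and_determinism(self, nussinov):
        spec = FeatureSpec(tiers="A", extended=True, backend="nussinov")
        assert len(spec.names) == len(TIER_A) + len(NEW_FEATURES)
        recs = [
            SequenceRecord(id="a", seq="GGGGGAAAACCCCCUUUAG"),
            SequenceRecord(id="b", seq="GGGGGAAAACCCCCUUUAG"),
        ]
        table, failures = extract(recs, spec, seed=5, backend=nussinov)
        assert not failures
        assert list(table.columns) == list(spec.names)
        assert np.array_equal(table.loc["a"].to_numpy(), table.loc["b"].to_numpy())

    def test_n_records_collected_not_fatal(self, nussinov):
        spec = FeatureSpec(tiers="A", extended=True, backend="nussinov")
        recs = [
            SequenceRecord(id="good", seq="GGGGGAAAACCCCC"),
            SequenceRecord(id="gapped", seq="GGGGGNAAACCCCC"),
        ]
        table, failures = extract(recs, spec, seed=0, backend=nussinov)
        assert list(table.index) == ["good"]
        assert failures and failures[0][0] == "gapped"

    def test_tsv_round_trip_12_digits(self, tmp_path, nussinov):
        spec = FeatureSpec(tiers="A", extended=True, backend="nussinov")
        recs = [SequenceRecord(id=f"r{i}", seq="GCAU" * 5 + "GGGAAACCC")
                for i in range(3)]
        table, _ = extract(recs, spec, seed=0, backend=nussinov)
        p = tmp_path / "feat.tsv"
        write_feature_tsv(table, p)
        back = read_feature_tsv(p)
        np.testing.assert_allclose(
            back.to_numpy(), table.to_numpy(), rtol=1e-12, atol=1e-15
        )

    def test_backend_mismatch_refused(self, nussinov):
        spec = FeatureSpec(tiers="A", extended=True, backend="vienna")
        with pytest.raises(FeatureError, match="backend mismatch"):
            extract([SequenceRecord(id="a", seq="GGGGGAAAACCCCC")], spec,
                    backend=nussinov)
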