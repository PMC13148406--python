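import math
import subprocess

import numpy as np
import pytest
from helpers import enumerate_glocal_scores, random_profile

from markerphylo.errors import FormatError, InputError, ValidationError
from markerphylo.profile_hmm import (
    AMINO20,
    ProfileHMM,
    ScoreThreshold,
    WorkerPlan,
    build_hmm,
    forward_bits,
    plan_search_workers,
    read_hmm,
    search_sample,
    viterbi,
    write_hmm,
)


def assert_models_close(a: ProfileHMM, b: ProfileHMM, tol=1e-5):
    assert a.marker_id == b.marker_id
    assert a.alphabet == b.alphabet
    assert a.model_length == b.model_length
    np.testing.assert_allclose(a.match_emission, b.match_emission, atol=tol)
    np.testing.assert_allclose(a.insert_emission, b.insert_emission, atol=tol)
    np.testing.assert_allclose(a.transitions, b.transitions, atol=tol)
    np.testing.assert_allclose(a.null_freq, b.null_freq, atol=tol)


class TestHmmIO:
    @pytest.mark.parametrize("M", [1, 5, 17])
    def test_write_read_roundtrip(self, rng, tmp_path, M):
        model = random_profile(rng, M, "amino20")
        path = tmp_path / "m.hmm"
        write_hmm(model, path)
        (back,) = read_hmm(path)
        assert_models_close(model, back)

    def test_zero_probability_written_as_star(self, rng, tmp_path):
        model = random_profile(rng, 3, "dna4")
        model.match_emission[1] = [0.0, 0.5, 0.5, 0.0]
        path = tmp_path / "m.hmm"
        write_hmm(model, path)
        assert "*" in path.read_text()
        (back,) = read_hmm(path)
        assert back.match_emission[1][0] == 0.0
        np.testing.assert_allclose(back.match_emission[1], model.match_emission[1], atol=1e-5)

    def test_uniform_neg_ln_encoding_recovered(self, tmp_path):
        """A file hand-encoding ln(1/20) in every match field parses to 0.05."""
        model = build_hmm(["ACDEF", "ACDEF"], pseudocount=1e12)  # ~uniform emissions
        path = tmp_path / "u.hmm"
        write_hmm(model, path)
        val = f"{-math.log(1.0 / 20):.5f}"
        assert val in path.read_text()
        (back,) = read_hmm(path)
        np.testing.assert_allclose(back.match_emission, 0.05, atol=1e-5)

    def test_truncated_record_is_format_error(self, rng, tmp_path):
        model = random_profile(rng, 4, "amino20")
        path = tmp_path / "m.hmm"
        write_hmm(model, path)
        text = path.read_text().splitlines()
        (tmp_path / "trunc.hmm").write_text("\n".join(text[:-2]) + "\n")
        with pytest.raises(FormatError):
            read_hmm(tmp_path / "trunc.hmm")

    def test_malformed_header_and_fields(self, tmp_path):
        bad = tmp_path / "bad.hmm"
        bad.write_text("NOTHMM stuff\n//\n")
        with pytest.raises(FormatError):
            read_hmm(bad)
        good = tmp_path / "m.hmm"
        write_hmm(build_hmm(["ACDE"]), good)
        corrupted = good.read_text().replace("  1  ", "  1  oops ", 1)
        (tmp_path / "c.hmm").write_text(corrupted)
        with pytest.raises(FormatError, match="line"):
            read_hmm(tmp_path / "c.hmm")

    def test_write_rejects_unnormalised_model(self, rng, tmp_path):
        model = random_profile(rng, 2, "dna4")
        model.match_emission[0] = [0.9, 0.9, 0.1, 0.1]
        with pytest.raises(ValidationError):
            write_hmm(model, tmp_path / "x.hmm")

    def test_hmmbuild_output_is_parseable(self, tmp_path):
        """Interoperability: profiles built by HMMER's own hmmbuild parse
        into valid models with the right length."""
        sto = tmp_path / "seed.sto"
        sto.write_text(
            "# STOCKHOLM 1.0\n"
            "s1 ACDEFGHIKL\n"
            "s2 ACDEFGHIKL\n"
            "s3 ACDEYGHIKL\n"
            "//\n"
        )
        out = tmp_path / "seed.hmm"
        res = subprocess.run(
            ["hmmbuild", "--amino", str(out), str(sto)], capture_output=True, text=True
        )
        assert res.returncode == 0, res.stderr
        (model,) = read_hmm(out)
        assert model.model_length == 10
        assert model.alphabet == "amino20"
        model.validate(atol=1e-3)

    def test_written_files_parse_with_pyhmmer(self, rng, tmp_path):
        pyhmmer = pytest.importorskip("pyhmmer")
        model = random_profile(rng, 6, "amino20")
        path = tmp_path / "m.hmm"
        write_hmm(model, path)
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            hmms = list(fh)
        assert len(hmms) == 1 and hmms[0].M == 6


class TestBuildHmm:
    def test_pseudocount_formula_single_sequence(self):
        model = build_hmm(["ACDE"], pseudocount=1.0)
        assert model.model_length == 4
        a_idx = AMINO20.index("A")
        assert model.match_emission[0][a_idx] == pytest.approx(2 / 21)
        # unobserved residue
        assert model.match_emission[0][AMINO20.index("C")] == pytest.approx(1 / 21)

    def test_majority_gap_column_excluded(self):
        model = build_hmm(["A-CD", "A-CD", "AEC-"], pseudocount=1.0)
        # column 2 is 2/3 gaps -> excluded; column 4 is 1/3 gaps -> kept
        assert model.model_length == 3

    def test_zero_pseudocount_gives_deterministic_emissions(self):
        model = build_hmm(["ACD", "ACD", "ACD"], pseudocount=0.0)
        assert model.match_emission[0][AMINO20.index("A")] == 1.0
        assert model.match_emission[0].sum() == pytest.approx(1.0)

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(InputError):
            build_hmm(["--", "--"])


class TestScoring:
    def test_dp_matches_path_enumeration(self, rng):
        """Viterbi and forward agree with brute-force enumeration over all
        glocal state paths on small random models."""
        for _ in range(60):
            M = int(rng.integers(1, 4))
            model = random_profile(rng, M, "dna4")
            L = int(rng.integers(1, 5))
            seq = "".join(rng.choice(list("ACGT"), L))
            v_oracle, f_oracle = enumerate_glocal_scores(model, seq)
            v_bits, path = viterbi(model, seq)
            f_bits = forward_bits(model, seq)
            assert v_bits == pytest.approx(v_oracle, abs=1e-9)
            assert f_bits == pytest.approx(f_oracle, abs=1e-9)
            assert path.states[0] == "B" and path.states[-1] == "E"

    def test_forward_dominates_viterbi(self, rng):
        for _ in range(100):
            model = random_profile(rng, int(rng.integers(1, 6)), "amino20")
            L = int(rng.integers(1, 12))
            seq = "".join(rng.choice(list(AMINO20), L))
            v, _ = viterbi(model, seq)
            assert forward_bits(model, seq) >= v - 1e-9

    def test_consensus_sequence_takes_pure_match_path(self):
        rows = ["MKVLH"] * 6
        model = build_hmm(rows, pseudocount=0.01)
        bits, path = viterbi(model, "MKVLH")
        assert [s for s, _ in path.steps] == ["M"] * 5
        assert [k for _, k in path.steps] == [1, 2, 3, 4, 5]
        assert bits > 0

    def test_single_path_model_forward_equals_viterbi(self):
        """With deterministic transitions and emissions the path sum
        collapses onto the single allowed path."""
        K = 4
        match = np.zeros((2, K))
        match[0][0] = 1.0  # A
        match[1][1] = 1.0  # C
        insert = np.full((2, K), 1.0 / K)
        trans = np.array([
            [1, 0, 0, 1, 0, 1, 0],
            [1, 0, 0, 1, 0, 1, 0],
            [1, 0, 0, 1, 0, 1, 0],
        ], dtype=float)
        model = ProfileHMM("one", "dna4", match, insert, trans, np.full(K, 0.25))
        model.validate()
        v, path = viterbi(model, "AC")
        f = forward_bits(model, "AC")
        assert v == pytest.approx(f, abs=1e-9)
        assert v == pytest.approx(math.log2(4.0) * 2)  # two 1.0-emissions vs 0.25 null

    def test_model_samples_outscore_their_shuffles(self, rng):
        """Sequences following the model's consensus should score higher
        than residue-shuffled versions of themselves (median over draws)."""
        rows = ["".join(rng.choice(list(AMINO20), 40)) for _ in range(1)] * 8
        model = build_hmm(rows, pseudocount=0.1)
        diffs = []
        for _ in range(50):
            # sample from match emissions
            seq = "".join(
                AMINO20[rng.choice(20, p=model.match_emission[k])]
                for k in range(model.model_length)
            )
            shuffled = "".join(rng.permutation(list(seq)))
            diffs.append(forward_bits(model, seq) - forward_bits(model, shuffled))
        assert np.median(diffs) > 0

    def test_empty_and_bad_residue_rejected(self, rng):
        model = random_profile(rng, 3, "dna4")
        with pytest.raises(InputError):
            viterbi(model, "")
        with pytest.raises(InputError):
            forward_bits(model, "ACX")


class TestSearch:
    def _write_fasta(self, path, records):
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))

    def test_planted_sequence_is_top_hit(self, rng, tmp_path):
        rows = ["".join(rng.choice(list(AMINO20), 60)) for _ in range(1)] * 6
        model = build_hmm(rows, pseudocount=0.2, marker_id="mkX")
        planted = rows[0]
        decoys = [(f"d{i}", "".join(rng.choice(list(AMINO20), 60))) for i in range(50)]
        fasta = tmp_path / "sample.faa"
        self._write_fasta(fasta, [("planted", planted)] + decoys)
        hits = search_sample([model], fasta, ScoreThreshold(floor_bits=10.0))
        assert hits, "planted sequence not found"
        best = max(hits, key=lambda h: h.bit_score)
        assert best.seq_id == "planted"
        assert best.model_span == (1, model.model_length)
        # exact (unfiltered) search agrees
        exact = search_sample([model], fasta, ScoreThreshold(floor_bits=10.0), prefilter=False)
        assert {h.seq_id for h in exact} == {h.seq_id for h in hits}

    def test_threshold_above_all_scores_yields_nothing(self, rng, tmp_path):
        model = build_hmm(["MKVLHEWAAR"] * 4, pseudocount=0.1)
        fasta = tmp_path / "s.faa"
        self._write_fasta(fasta, [("a", "MKVLHEWAAR")])
        assert search_sample([model], fasta, ScoreThreshold(floor_bits=1e6)) == []

    def test_two_gene_copies_both_recorded(self, rng, tmp_path):
        rows = ["".join(rng.choice(list(AMINO20), 50))] * 5
        model = build_hmm(rows, pseudocount=0.2, marker_id="mkY")
        fasta = tmp_path / "s.faa"
        self._write_fasta(fasta, [("copy1", rows[0]), ("copy2", rows[0])])
        hits = search_sample([model], fasta)
        assert sorted(h.seq_id for h in hits) == ["copy1", "copy2"]

    def test_gathering_cutoff_preferred_over_floor(self, rng, tmp_path):
        rows = ["".join(rng.choice(list(AMINO20), 50))] * 5
        model = build_hmm(rows, pseudocount=0.2)
        model.gathering_cutoff_bits = 1e6
        fasta = tmp_path / "s.faa"
        self._write_fasta(fasta, [("a", rows[0])])
        assert search_sample([model], fasta, ScoreThreshold(floor_bits=10.0)) == []

    def test_empty_fasta_rejected(self, tmp_path, rng):
        model = random_profile(rng, 3, "amino20")
        empty = tmp_path / "e.faa"
        empty.write_text("")
        with pytest.raises(InputError):
            search_sample([model], empty)


class TestWorkerPlan:
    @pytest.mark.parametrize("n,expected", [
        (1, (1, 1)), (4, (1, 4)), (7, (1, 7)),
        (8, (2, 4)), (9, (2, 4)), (16, (4, 4)), (32, (8, 4)),
    ])
    def test_allocation_rule(self, n, expected):
        plan = plan_search_workers(n)
        assert (plan.n_instances, plan.cores_per_instance) == expected
        assert plan.n_instances * plan.cores_per_instance <= n

    def test_invalid_cpu_count(self):
        with pytest.raises(InputError):
            plan_search_workers(0)
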