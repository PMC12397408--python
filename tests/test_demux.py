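"""Barcode caller: k-mer index, poly(T) detection, local alignment, calling."""

import numpy as np
import pytest

from beadsplice.demux import (
    BarcodeCaller,
    KmerIndex,
    build_kmer_index,
    call_barcode,
    classify_failure,
    find_polyT,
    local_align,
)
from beadsplice.io import Whitelist
from beadsplice.layout import MoleculeLayout
from beadsplice.sim import (
    NO_ERRORS,
    NO_TRUNCATION,
    ErrorModel,
    SimConfig,
    make_molecule,
    make_whitelist,
    simulate_dataset,
)


# --- independent oracles ---------------------------------------------------


def sw_score_oracle(q: str, t: str) -> int:
    """Textbook full-DP Smith-Waterman, score only (+1/-1/-1)."""
    H = [[0] * (len(t) + 1) for _ in range(len(q) + 1)]
    best = 0
    for i in range(1, len(q) + 1):
        for j in range(1, len(t) + 1):
            diag = H[i - 1][j - 1] + (1 if q[i - 1] == t[j - 1] else -1)
            H[i][j] = max(0, diag, H[i - 1][j] - 1, H[i][j - 1] - 1)
            best = max(best, H[i][j])
    return best


def rand_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


# --- k-mer index -----------------------------------------------------------


class TestKmerIndex:
    def test_single_sequence_single_key(self):
        idx = build_kmer_index({"ACGTAC"}, k=6)
        assert set(idx.table) == {"ACGTAC"}
        assert idx.lookup("ACGTAC") == {"ACGTAC"}

    def test_no_shared_kmer_empty_candidates(self):
        idx = build_kmer_index({"AAAAAA"}, k=6)
        assert idx.lookup("CCCCCCCCCC") == set()

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_index({"ACG"}, k=6)

    def test_candidates_equal_bruteforce_shared_kmer_scan(self, rng):
        barcodes = {rand_seq(rng, 14) for _ in range(1000)}
        k = 6
        idx = build_kmer_index(barcodes, k)
        for _ in range(50):
            query = rand_seq(rng, rng.integers(8, 20))
            qk = {query[i : i + k] for i in range(len(query) - k + 1)}
            expected = {
                b for b in barcodes
                if any(b[i : i + k] in qk for i in range(len(b) - k + 1))
            }
            assert idx.lookup(query) == expected

    def test_csr_index_matches_python_index(self, rng):
        from beadsplice import _engine

        barcodes = sorted({rand_seq(rng, 14) for _ in range(300)})
        codes = _engine.encode_barcodes(barcodes)
        offsets, values = _engine.build_csr_kmer_index(codes, 6)
        idx = build_kmer_index(barcodes, 6)
        from beadsplice._seq import encode

        lastseen = np.full(len(barcodes), -1, dtype=np.int64)
        out = np.empty(len(barcodes), dtype=np.int32)
        for stamp in range(1, 30):
            query = rand_seq(rng, 14)
            n = _engine.collect_candidates(
                encode(query), 6, offsets, values, lastseen, stamp, out
            )
            got = {barcodes[i] for i in out[:n]}
            assert got == idx.lookup(query)


# --- poly(T) detection -----------------------------------------------------


class TestFindPolyT:
    def test_clean_t_run_found(self, rng):
        left = rand_seq(rng, 40).replace("T", "A")
        right = rand_seq(rng, 60).replace("T", "A")
        seq = left + "T" * 30 + right
        assert find_polyT(seq) == (40, 70)

    def test_all_a_absent(self):
        assert find_polyT("A" * 100) is None

    def test_scattered_substitutions_still_detected(self):
        run = list("T" * 30)
        run[7] = "G"
        run[19] = "C"
        seq = "ACGACGACGACG" + "".join(run) + "GCAGCAGCA"
        hit = find_polyT(seq, window=16, min_frac_T=0.8)
        assert hit is not None
        s, e = hit
        assert s >= 12 and e <= 42

    def test_agrees_with_bruteforce_window_scan(self, rng):
        window, min_frac, min_t = 16, 0.8, 12
        need = -(-int(min_frac * window) // 1)
        import math

        need = math.ceil(min_frac * window)
        for _ in range(200):
            seq = "".join(
                "T" if u < 0.45 else "ACG"[int(3 * v)]
                for u, v in zip(rng.random(80), rng.random(80))
            )
            # oracle: leftmost qualifying window, trimmed to T, extended, T-count check
            expected = None
            for s in range(len(seq) - window + 1):
                if seq[s : s + window].count("T") >= need:
                    a, b = s, s + window
                    while a < b and seq[a] != "T":
                        a += 1
                    while b > a and seq[b - 1] != "T":
                        b -= 1
                    while a > 0 and seq[a - 1] == "T":
                        a -= 1
                    while b < len(seq) and seq[b] == "T":
                        b += 1
                    if seq[a:b].count("T") >= min_t:
                        expected = (a, b)
                    break
            assert find_polyT(seq, window, min_frac, min_t) == expected


# --- local alignment -------------------------------------------------------


class TestLocalAlign:
    def test_identity_scores_barcode_length(self):
        bc = "ACGTACGTACGTAA"
        score, tspan, qspan = local_align(bc, bc)
        assert score == 14
        assert tspan == (0, 14) and qspan == (0, 14)

    def test_internal_substitution_costs_two(self):
        bc = "ACGTACGTACGTAA"
        mut = bc[:7] + {"A": "C", "C": "A"}.get(bc[7], "A") + bc[8:]
        assert local_align(bc, mut)[0] == 12

    def test_terminal_substitution_costs_one(self):
        # the aligner clips the mismatching last base instead of paying for it
        bc = "ACGTACGTACGTAA"
        mut = bc[:-1] + "C"
        assert local_align(bc, mut)[0] == 13

    def test_matches_full_dp_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            q = rand_seq(rng, rng.integers(10, 31))
            t = rand_seq(rng, rng.integers(10, 31))
            assert local_align(q, t)[0] == sw_score_oracle(q, t)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")


# --- end-to-end calling ----------------------------------------------------


@pytest.fixture(scope="module")
def wl200():
    return make_whitelist(200, 14, np.random.default_rng(7))


@pytest.fixture(scope="module")
def caller200(wl200):
    return BarcodeCaller(wl200, MoleculeLayout(), min_score=13)


class TestCallBarcode:
    def test_error_free_read_full_score_and_umi(self, wl200, caller200, rng):
        layout = MoleculeLayout()
        bc = wl200.barcodes[17]
        umi = "ACGTACGCA"
        mol = make_molecule(rand_seq(rng, 300), bc, umi, layout)
        call = caller200.call("m1", mol)
        assert call.called and call.barcode == bc
        assert call.score == 14
        assert call.umi == umi
        assert call.strand_used == "forward"
        assert classify_failure(call) == "ok"

    def test_reverse_complement_read_recovered(self, wl200, caller200, rng):
        from beadsplice._seq import revcomp

        bc = wl200.barcodes[3]
        mol = make_molecule(rand_seq(rng, 300), bc, "ACGTACGCA", MoleculeLayout())
        call = caller200.call("m2", revcomp(mol))
        assert call.called and call.barcode == bc
        assert call.strand_used == "reverse"

    def test_truncation_through_barcode_gives_no_call(self, wl200, caller200, rng):
        layout = MoleculeLayout()
        mol = make_molecule(rand_seq(rng, 300), wl200.barcodes[0], "ACGTACGCA", layout)
        truncated = mol[len(layout.primer_seq) + 30 :]  # barcode region gone
        call = caller200.call("m3", truncated)
        assert not call.called

    def test_min_score_above_barcode_length_is_config_error(self, wl200):
        with pytest.raises(ValueError, match="min_score"):
            BarcodeCaller(wl200, MoleculeLayout(), min_score=15)

    def test_call_equals_bruteforce_whole_whitelist_alignment(self, rng):
        # errors off: every called barcode must equal the best full-whitelist
        # local alignment of the extracted region; with a unique top score the
        # call is made, and it matches the embedded truth by construction
        wl = make_whitelist(300, 14, rng)
        cfg = SimConfig(
            n_molecules=60, n_barcodes=300, whitelist=wl,
            errors=NO_ERRORS, truncation=NO_TRUNCATION, seed=11,
        )
        ds = simulate_dataset(cfg, rng)
        caller = BarcodeCaller(wl, ds.layout, min_score=13)
        for rid, codes, truth in zip(ds.read_ids, ds.sequences, ds.truth):
            call = caller.call_encoded(rid, codes)
            assert call.called and call.score == 14
            assert call.barcode == truth.true_barcode
            # brute force over the whole whitelist on the extracted candidate:
            # barcode_span is the outer span (part1 + linker + part2) on the
            # oriented read, so splice out the linker to rebuild the candidate
            from beadsplice._seq import decode, revcomp

            seq = decode(codes)
            oriented_seq = seq if call.strand_used == "forward" else revcomp(seq)
            b_s, b_e = call.barcode_span
            l_s, l_e = call.linker_span
            cand = oriented_seq[b_s:l_s] + oriented_seq[l_e:b_e]
            best = max(sw_score_oracle(b, cand) for b in wl.barcodes)
            assert best == 14
            winners = [b for b in wl.barcodes if sw_score_oracle(b, cand) == best]
            assert winners == [call.barcode]

    def test_one_shot_wrapper(self, wl200, rng):
        bc = wl200.barcodes[5]
        mol = make_molecule(rand_seq(rng, 200), bc, "CCCCCCCAA", MoleculeLayout())
        assert call_barcode(("r", mol), wl200).barcode == bc


class TestClassifyFailure:
    def test_all_a_read_fails_at_polyt(self, caller200):
        assert classify_failure(caller200.call("x", "A" * 200)) == "no_polyT"

    def test_missing_linker_detected(self, wl200, caller200, rng):
        layout = MoleculeLayout()
        bc = wl200.barcodes[9]
        # hand-assemble without the linker
        mol = (
            layout.primer_seq + bc + "ACGTACGTA" + "T" * 30 + rand_seq(rng, 200).replace("T", "A")
        )
        assert classify_failure(caller200.call("x", mol)) == "no_linker"

    def test_stage_counts_sum_to_total(self, rng):
        wl = make_whitelist(300, 14, rng)
        ds = simulate_dataset(
            SimConfig(n_molecules=300, n_barcodes=300, whitelist=wl, seed=5), rng
        )
        caller = BarcodeCaller(wl, ds.layout, min_score=13)
        counts = {}
        for rid, codes in zip(ds.read_ids, ds.sequences):
            c = caller.call_encoded(rid, codes)
            counts[c.failure] = counts.get(c.failure, 0) + 1
        assert sum(counts.values()) == len(ds)
        assert counts.get("ok", 0) > 0


class TestThresholdMonotonicity:
    def test_raising_cutoff_never_adds_calls(self, rng):
        wl = make_whitelist(500, 14, rng)
        ds = simulate_dataset(
            SimConfig(n_molecules=300, n_barcodes=500, whitelist=wl, seed=6), rng
        )
        called = {}
        for ms in (11, 13):
            caller = BarcodeCaller(wl, ds.layout, min_score=ms)
            called[ms] = {
                c.read_id
                for c in (
                    caller.call_encoded(r, s) for r, s in zip(ds.read_ids, ds.sequences)
                )
                if c.called
            }
        assert called[13] <= called[11]

    def test_umi_length_recorded_as_observed(self, wl200, caller200, rng):
        # deletion inside the UMI shortens the recorded UMI; no correction here
        layout = MoleculeLayout()
        bc = wl200.barcodes[30]
        umi = "ACGTACGCA"
        mol = make_molecule(rand_seq(rng, 150), bc, umi, layout)
        # delete one UMI base by hand
        pos = len(layout.primer_seq) + 8 + len(layout.linker_seq) + 6 + 4
        broken = mol[:pos] + mol[pos + 1 :]
        call = caller200.call("m", broken)
        if call.called:
            assert len(call.umi) == 8
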