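"""Sequencing decode stages: registration, unmixing, basecalling,
codebook correction, cell counts, round detection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from exmpipe import exseq, synthetic
from exmpipe.exseq import Codebook
from exmpipe.types import RegistrationError, SegmentationMap


class TestCodebook:
    def test_default_has_correction_capacity(self, codebook):
        assert len(codebook.barcodes) == 87
        assert codebook.barcode_length == 7
        assert codebook.min_pairwise_hamming >= 3

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            Codebook(
                barcodes={"A1": "ACGTACG", "B1": "ACGTACG"},
                channel_to_base=synthetic.CHANNEL_TO_BASE,
            )

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError):
            Codebook(
                barcodes={"A1": "ACGTACG", "B1": "ACGT"},
                channel_to_base=synthetic.CHANNEL_TO_BASE,
            )

    def test_lowercase_normalized(self):
        cb = Codebook(
            barcodes={"A1": "acgtacg"},
            channel_to_base=synthetic.CHANNEL_TO_BASE,
        )
        assert cb.barcodes["A1"] == "ACGTACG"


class TestRegisterRounds:
    def test_zero_drift_zero_shifts(self, codebook):
        stacks, _, _ = synthetic.gen_exseq_stacks(
            codebook, n_amplicons=50, drift_px=0.0, seed=1
        )
        _, shifts, _ = exseq.register_rounds(stacks)
        assert np.abs(shifts).max() < 0.05

    def test_known_drift_recovered(self, codebook):
        stacks, _, truth = synthetic.gen_exseq_stacks(
            codebook, n_amplicons=50, drift_px=3.0, seed=2
        )
        _, shifts, _ = exseq.register_rounds(stacks)
        assert np.abs(shifts - truth.truth_tables["drifts"]).max() <= 0.2

    def test_fiducial_free_stacks_fail(self, codebook):
        stacks, _, _ = synthetic.gen_exseq_stacks(
            codebook, n_amplicons=20, n_fiducials=0, seed=3
        )
        with pytest.raises(RegistrationError):
            exseq.register_rounds(stacks)


class TestColorCorrect:
    def test_identity_is_noop(self, rng):
        stack = rng.random((4, 32, 32))
        corrected, clipped = exseq.color_correct(stack, np.eye(4))
        assert np.allclose(corrected, stack)
        assert clipped == 0.0

    def test_known_mixing_inverted(self, rng):
        clean = rng.random((4, 32, 32))
        M = np.full((4, 4), 0.08) + np.eye(4) * 0.7
        mixed = np.einsum("ij,jhw->ihw", M, clean)
        corrected, _ = exseq.color_correct(mixed, M)
        rms = np.sqrt(np.mean((corrected - clean) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(clean**2))

    def test_ill_conditioned_rejected(self):
        M = np.ones((4, 4)) + 1e-9 * np.eye(4)
        with pytest.raises(ValueError):
            exseq.color_correct(np.zeros((4, 8, 8)), M)


class TestSegmentAmplicons:
    def test_blank_stack_empty(self):
        puncta, intensities = exseq.segment_amplicons(np.zeros((7, 4, 64, 64)))
        assert len(puncta) == 0 and intensities.shape[0] == 0

    def test_counts_and_positions_zero_noise(self, codebook):
        stacks, _, truth = synthetic.gen_exseq_stacks(
            codebook, n_amplicons=100, n_fiducials=0, seed=4
        )
        puncta, _ = exseq.segment_amplicons(stacks)
        true_pos = truth.truth_tables["reads"][["y", "x"]].to_numpy()
        assert len(puncta) == 100
        from scipy.spatial import cKDTree

        d, _ = cKDTree(true_pos).query(puncta[["y", "x"]].to_numpy())
        assert d.max() <= 1.0

    def test_closer_than_suppression_radius_merges(self):
        stacks = np.zeros((2, 4, 64, 64))
        for pos in ((32.0, 32.0), (32.0, 33.5)):  # < 2 * psf_sigma apart
            for r in range(2):
                yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
                stacks[r, 0] += 100 * np.exp(
                    -((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2) / (2 * 1.2**2)
                )
        puncta, _ = exseq.segment_amplicons(stacks, psf_sigma=1.2)
        assert len(puncta) == 1


class TestBasecall:
    def test_clean_one_hot(self, codebook):
        base_to_channel = {b: c for c, b in codebook.channel_to_base.items()}
        barcode = "ACTGACT"
        intensities = np.zeros((1, 7, 4))
        for r, b in enumerate(barcode):
            intensities[0, r, base_to_channel[b]] = 10.0
        calls, margins, ties = exseq.basecall(
            intensities, codebook.channel_to_base
        )
        assert calls[0] == barcode
        assert np.all(margins == 10.0)
        assert not ties.any()

    def test_tie_flagged_and_deterministic(self, codebook):
        intensities = np.zeros((1, 1, 4))
        intensities[0, 0, [1, 2]] = 5.0
        calls, margins, ties = exseq.basecall(
            intensities, codebook.channel_to_base
        )
        assert ties[0, 0]
        assert calls[0] == codebook.channel_to_base[1]  # lowest channel wins

    def test_all_zero_round_is_n(self, codebook):
        calls, margins, _ = exseq.basecall(
            np.zeros((1, 3, 4)), codebook.channel_to_base
        )
        assert calls[0] == "NNN"
        assert np.all(margins == 0.0)

    def test_per_round_error_rate_matches_simulation(self, codebook):
        stacks, _, truth = synthetic.gen_exseq_stacks(
            codebook, base_error_rate=0.05, n_fiducials=0, seed=5
        )
        puncta, intensities = exseq.segment_amplicons(stacks)
        calls, _, _ = exseq.basecall(intensities, codebook.channel_to_base)
        reads = truth.truth_tables["reads"]
        from scipy.spatial import cKDTree

        tree = cKDTree(reads[["y", "x"]].to_numpy())
        _, idx = tree.query(puncta[["y", "x"]].to_numpy())
        n_wrong = sum(
            sum(a != b for a, b in zip(c, reads["barcode"].iloc[i]))
            for c, i in zip(calls, idx)
        )
        n_total = len(calls) * codebook.barcode_length
        rate = n_wrong / n_total
        se = np.sqrt(0.05 * 0.95 / n_total)
        assert abs(rate - 0.05) < 3 * se


class TestMatchCodebook:
    def test_exact_match(self, codebook):
        gene, barcode = next(iter(codebook.barcodes.items()))
        assert exseq.match_codebook(barcode, codebook) == (gene, 0)

    def test_all_single_corruptions_corrected(self, codebook):
        alphabet = "ACGT"
        for gene, barcode in codebook.barcodes.items():
            for pos in range(len(barcode)):
                for wrong in alphabet:
                    if wrong == barcode[pos]:
                        continue
                    corrupted = barcode[:pos] + wrong + barcode[pos + 1 :]
                    matched, used = exseq.match_codebook(corrupted, codebook, 1)
                    assert matched == gene and used == 1

    def test_double_corruption_never_silently_wrong(self, codebook):
        # at radius 1 a double error either misses or lands within
        # distance 1 of some other codeword — it must never match a wrong
        # gene from farther away
        rng = np.random.default_rng(0)
        alphabet = "ACGT"
        genes = list(codebook.barcodes)
        for gene in rng.choice(genes, size=15, replace=False):
            barcode = codebook.barcodes[gene]
            for p1, p2 in itertools.combinations(range(len(barcode)), 2):
                for w1 in alphabet:
                    for w2 in alphabet:
                        if w1 == barcode[p1] or w2 == barcode[p2]:
                            continue
                        corrupted = list(barcode)
                        corrupted[p1], corrupted[p2] = w1, w2
                        corrupted = "".join(corrupted)
                        matched, used = exseq.match_codebook(
                            corrupted, codebook, 1
                        )
                        if matched is not None and matched != gene:
                            other = codebook.barcodes[matched]
                            dist = sum(
                                a != b for a, b in zip(corrupted, other)
                            )
                            assert dist <= 1

    def test_radius_beyond_capacity_rejected(self, codebook):
        with pytest.raises(ValueError):
            exseq.match_codebook("AAAAAAA", codebook, radius=2)


class TestReadsToCells:
    def test_background_read_excluded_from_matrix(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4:10, 4:10] = 1
        seg = SegmentationMap(labels)
        reads = pd.DataFrame(
            dict(y=[6.0, 14.0], x=[6.0, 14.0], matched_gene=["G1", "G1"])
        )
        out, matrix = exseq.reads_to_cells(reads, seg, genes=["G1"])
        assert list(out["cell_id"]) == [1, 0]
        assert matrix.loc[1, "G1"] == 1
        assert matrix.to_numpy().sum() == 1

    def test_zero_noise_matrix_equals_truth(self, codebook):
        stacks, seg, truth = synthetic.gen_exseq_stacks(codebook, seed=6)
        reads, matrix = exseq.decode_stacks(
            stacks, codebook, seg=seg, register=False
        )
        tr = truth.truth_tables["reads"]
        expected = (
            tr[tr["cell_id"] > 0]
            .groupby(["cell_id", "gene"])
            .size()
            .unstack(fill_value=0)
            .reindex(index=seg.label_ids, columns=codebook.genes, fill_value=0)
        )
        assert (matrix.to_numpy() == expected.to_numpy()).all()
        # conservation: every punctum carries a terminal status
        assert set(reads["status"]) <= {"matched", "unmatched", "fiducial"}
        assert (
            matrix.sum(axis=1).to_numpy()
            == reads[(reads["status"] == "matched") & (reads["cell_id"] > 0)]
            .groupby("cell_id")
            .size()
            .reindex(seg.label_ids, fill_value=0)
            .to_numpy()
        ).all()


class TestRoundDetectionRate:
    def test_identical_rounds_full_rate(self, rng):
        ref = rng.uniform(0, 100, (50, 2))
        rates, mean = exseq.round_detection_rate(ref, [ref, ref, ref])
        assert np.all(rates == 1.0) and mean == 1.0

    def test_dropout_rate_within_3_se(self, codebook):
        stacks, _, truth = synthetic.gen_exseq_stacks(
            codebook, dropout_rate=0.05, n_fiducials=0, seed=8
        )
        ref = truth.truth_tables["reads"][["y", "x"]].to_numpy()
        per_round = []
        for r in range(stacks.shape[0]):
            puncta, _ = exseq.segment_amplicons(stacks[r : r + 1])
            per_round.append(puncta[["y", "x"]].to_numpy())
        rates, mean = exseq.round_detection_rate(ref, per_round)
        n = len(ref) * len(per_round)
        se = np.sqrt(0.95 * 0.05 / n)
        assert abs(mean - 0.95) < 3 * se

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            exseq.round_detection_rate(np.empty((0, 2)), [np.zeros((3, 2))])
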