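"""Genomic binning, windowed CNV inference, and the hallmark-genotype call."""

import numpy as np
import pandas as pd
import pytest

from gbmcaf import (
    SimulationConfig,
    bin_genes,
    call_chromosome_events,
    infer_cnv,
    is_gbm_malignant,
    log_normalize,
    simulate_counts,
)
from gbmcaf.cnv import CNVProfile, GenomicBin
from gbmcaf.exceptions import GbmCafError, ParameterError

from conftest import make_norm


def annotation(rows):
    return pd.DataFrame(rows, columns=["gene", "chromosome", "start"])


class TestBinGenes:
    def test_half_open_interval_boundaries(self):
        ann = annotation([("a", "7", 0), ("b", "7", 999_999), ("c", "7", 1_000_000)])
        bins = bin_genes(ann)
        assert len(bins) == 2
        assert set(bins[0].member_genes) == {"a", "b"}
        assert bins[1].member_genes == ("c",)

    def test_bins_partition_default_annotation(self):
        lab = simulate_counts(SimulationConfig(n_cells=10, seed=0))
        bins = bin_genes(lab.gene_annotation)
        members = [g for b in bins for g in b.member_genes]
        assert len(members) == lab.counts.n_genes
        assert len(set(members)) == len(members)
        for b in bins:
            assert b.start < b.end

    def test_mixed_chromosome_naming_normalized_with_warning(self):
        ann = annotation([("a", "chr7", 0), ("b", "7", 2_000_000)])
        with pytest.warns(UserWarning, match="mixed"):
            bins = bin_genes(ann)
        assert {b.chromosome for b in bins} == {"7"}

    def test_empty_annotation_rejected(self):
        with pytest.raises(ParameterError):
            bin_genes(annotation([]))


def two_chrom_norm(n_cells=4, shift=None, seed=0):
    """Small matrix over chr7 and chr10 with controllable per-cell shifts."""
    rng = np.random.default_rng(seed)
    genes = [(f"g7_{i}", "7", i * 500_000) for i in range(12)] + [
        (f"g10_{i}", "10", i * 500_000) for i in range(12)
    ]
    ann = annotation(genes)
    base = rng.uniform(0.5, 2.0, len(genes))
    vals = np.tile(base, (n_cells, 1))
    if shift is not None:
        vals = vals + shift
    data = {g: vals[:, j] for j, (g, _, _) in enumerate(genes)}
    return make_norm(data), ann


class TestInferCnv:
    def test_identical_cells_give_zero_log_ratios(self):
        norm, ann = two_chrom_norm()
        prof = infer_cnv(norm, bin_genes(ann))
        assert np.allclose(prof.log_ratios, 0.0, atol=1e-12)

    def test_gene_order_within_bin_is_irrelevant(self):
        norm, ann = two_chrom_norm()
        prof1 = infer_cnv(norm, bin_genes(ann))
        prof2 = infer_cnv(norm, bin_genes(ann.iloc[::-1].reset_index(drop=True)))
        assert np.allclose(prof1.log_ratios, prof2.log_ratios)

    def test_shift_invariance_of_log_ratios(self):
        norm, ann = two_chrom_norm()
        prof = infer_cnv(norm, bin_genes(ann))
        shifted, _ = two_chrom_norm(shift=0.7)
        prof_shift = infer_cnv(shifted, bin_genes(ann))
        assert np.allclose(prof.log_ratios, prof_shift.log_ratios, atol=1e-12)

    def test_smoothed_values_stay_within_raw_envelope(self, default_run):
        norm = default_run.norm
        ann = default_run.labeled.gene_annotation
        bins = bin_genes(ann[ann["chromosome"] == "7"])
        raw = infer_cnv(norm, bins, smooth_span=1_000_000)  # window of one bin
        smooth = infer_cnv(norm, bins, smooth_span=5_000_000)
        lo = raw.log_ratios.min(axis=1) - 1e-9
        hi = raw.log_ratios.max(axis=1) + 1e-9
        assert np.all(smooth.log_ratios.min(axis=1) >= lo)
        assert np.all(smooth.log_ratios.max(axis=1) <= hi)

    def test_empty_reference_mask_rejected(self):
        norm, ann = two_chrom_norm()
        with pytest.raises(ParameterError):
            infer_cnv(norm, bin_genes(ann), reference=np.zeros(4, dtype=bool))

    def test_planted_gain_magnitude_near_log_fold(self, default_run):
        prof = default_run.profile_refnormal
        mal = (default_run.truth == "malignant").to_numpy()
        chr7 = prof.chromosome_of_bins() == "7"
        mean7 = prof.log_ratios[np.ix_(mal, chr7)].mean()
        assert mean7 == pytest.approx(np.log(1.5), rel=0.15)


def profile_from(vals, chroms, cells=("c0",)):
    bins = [
        GenomicBin(chromosome=c, start=i * 10 ** 6, end=(i + 1) * 10 ** 6, member_genes=(f"g{i}",))
        for i, c in enumerate(chroms)
    ]
    return CNVProfile(
        cell_ids=np.array(cells, dtype=object),
        bins=bins,
        log_ratios=np.asarray(vals, dtype=float),
        reference_description="synthetic",
    )


class TestCalls:
    def test_all_zero_profile_is_neutral(self):
        prof = profile_from([[0.0] * 6], ["7"] * 3 + ["10"] * 3)
        calls = call_chromosome_events(prof)
        assert (calls.loc["c0"] == "neutral").all()

    def test_uniform_gain_called(self):
        prof = profile_from([[0.4, 0.4, 0.4, 0.0, 0.0, 0.0]], ["7"] * 3 + ["10"] * 3)
        calls = call_chromosome_events(prof)
        assert calls.loc["c0", "7"] == "gain"
        assert calls.loc["c0", "10"] == "neutral"

    def test_single_bin_chromosome_warns(self):
        prof = profile_from([[0.4, 0.0]], ["7", "10"])
        with pytest.warns(UserWarning, match="single-bin"):
            call_chromosome_events(prof)

    def test_malignant_requires_conjunction(self):
        prof = profile_from(
            [[0.4, 0.4, 0.0, 0.0], [0.4, 0.4, -0.4, -0.4]],
            ["7", "7", "10", "10"],
            cells=("gain_only", "gain_and_loss"),
        )
        calls = call_chromosome_events(prof)
        assert list(is_gbm_malignant(calls)) == [False, True]

    def test_missing_hallmark_chromosome_is_hard_error(self):
        prof = profile_from([[0.4, 0.4]], ["7", "7"])
        calls = call_chromosome_events(prof)
        with pytest.raises(GbmCafError):
            is_gbm_malignant(calls)

    def test_default_run_flags_malignant_cells(self, default_run):
        mal = default_run.malignant_refnormal
        truth = (default_run.truth == "malignant").to_numpy()
        assert mal[truth].mean() >= 0.95
        assert 1.0 - mal[~truth].mean() >= 0.95


class TestMonotoneSensitivity:
    def test_detection_rate_nondecreasing_in_gain_fold(self):
        rates = []
        for fold in (1.1, 1.3, 1.5):
            cfg = SimulationConfig(n_cells=800, seed=21, cnv_gain_fold=fold)
            lab = simulate_counts(cfg)
            norm = log_normalize(lab.counts)
            ann = lab.gene_annotation
            bins = bin_genes(ann[ann["chromosome"] != "MT"])
            normal = (lab.truth_labels != "malignant").to_numpy()
            prof = infer_cnv(norm, bins, reference=normal)
            calls = call_chromosome_events(prof)
            mal_truth = ~normal
            rates.append((calls.loc[mal_truth, "7"] == "gain").mean())
        assert rates[0] <= rates[1] + 1e-9 <= rates[2] + 2e-9
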