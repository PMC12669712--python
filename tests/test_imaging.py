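"""Segmentation and morphometrics against generator ground truth and
analytic shape oracles."""

import dataclasses

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from hipposcaffold import imaging, synthetic
from hipposcaffold.imaging import (
    CellImage,
    DegenerateChannelError,
    estimate_effect,
    measure_cells,
    segment_cells,
    segment_nuclei,
    segment_stress_fibers,
)


def _match_instances(truth_mask, pred_mask):
    """Map each truth label to its best-overlap predicted label and IoU."""
    out = {}
    for t in np.unique(truth_mask)[1:]:
        tm = truth_mask == t
        labels, counts = np.unique(pred_mask[tm], return_counts=True)
        keep = labels > 0
        if not keep.any():
            out[int(t)] = (0, 0.0)
            continue
        best = labels[keep][np.argmax(counts[keep])]
        pm = pred_mask == best
        out[int(t)] = (int(best), float((tm & pm).sum() / (tm | pm).sum()))
    return out


def _flat_image(dna):
    zeros = np.zeros_like(dna, dtype=float)
    return CellImage(channels={"dna": dna.astype(float),
                               "actin": zeros.copy(), "protein": zeros.copy()})


class TestSegmentNuclei:
    def test_recovers_disjoint_nuclei_with_high_iou(self, clean_field):
        image, truth = clean_field
        pred = segment_nuclei(image)
        matches = _match_instances(truth.nuclei_mask, pred)
        assert len(matches) == truth.nuclei_mask.max()
        assert all(iou >= 0.95 for _, iou in matches.values())

    def test_blank_channel_is_degenerate(self):
        with pytest.raises(DegenerateChannelError):
            segment_nuclei(_flat_image(np.zeros((128, 128))))

    def test_bridged_nuclei_are_split_by_watershed(self):
        """Two disks fused by a thin bridge come out as two labels."""
        dna = np.zeros((128, 128))
        for cx in (45, 83):
            rr, cc = draw_disk((64, cx), 14)
            dna[rr, cc] = 200.0
        dna[63:65, 58:70] = 200.0  # 2-px bridge
        pred = segment_nuclei(_flat_image(dna))
        assert pred.max() == 2

    def test_small_components_removed(self):
        dna = np.zeros((128, 128))
        rr, cc = draw_disk((40, 40), 14)
        dna[rr, cc] = 200.0
        dna[100:103, 100:103] = 200.0  # 9 px < min_area
        pred = segment_nuclei(_flat_image(dna))
        assert pred.max() == 1


class TestSegmentCells:
    def test_recovers_cells_with_high_iou(self, clean_field):
        image, truth = clean_field
        nuclei = segment_nuclei(image)
        cells = segment_cells(image, nuclei)
        matches = _match_instances(truth.cell_mask, cells)
        assert all(iou >= 0.9 for _, iou in matches.values())

    def test_each_cell_contains_its_nucleus(self, noisy_field):
        image, _ = noisy_field
        nuclei = segment_nuclei(image)
        cells = segment_cells(image, nuclei)
        for k in range(1, nuclei.max() + 1):
            owners = np.unique(cells[nuclei == k])
            assert list(owners) == [k]

    def test_requires_nuclei(self, noisy_field):
        image, _ = noisy_field
        with pytest.raises(ValueError, match="no nuclei"):
            segment_cells(image, np.zeros(image.shape, dtype=np.int32))


class TestSegmentStressFibers:
    def test_fiberless_condition_yields_empty_mask(self, clean_wt_profile):
        profile = dataclasses.replace(clean_wt_profile, fiber_count_mean=0.0)
        image, truth = synthetic.generate_cell_image(profile, seed=2)
        fibers = segment_stress_fibers(image, truth.cell_mask)
        assert not fibers.any()

    def test_recovers_fiber_coverage_within_tolerance(self, clean_field):
        image, truth = clean_field
        fibers = segment_stress_fibers(image, truth.cell_mask)
        assert truth.fiber_mask.sum() > 0
        recall = (fibers & truth.fiber_mask).sum() / truth.fiber_mask.sum()
        assert recall > 0.9
        assert fibers.sum() == pytest.approx(truth.fiber_mask.sum(), rel=0.1)

    def test_known_fiber_lengths_recovered(self):
        """Three drawn 40-px fibers are measured at 40 +/- 3 px."""
        profile = synthetic.EffectProfile(
            condition_name="fib", cells_per_image=3, fiber_count_mean=1.0,
            fiber_length_mean=40.0, fiber_length_sd=0.0, noise_sd=0.0,
        )
        # fiber counts are Poisson; find a seed-independent check via truth
        image, truth = synthetic.generate_cell_image(profile, seed=6)
        fibers = segment_stress_fibers(image, truth.cell_mask)
        records = measure_cells(image, truth.nuclei_mask, truth.cell_mask,
                                fibers)
        lengths = [ln for r in records for ln in r.fiber_lengths]
        truth_lengths = [ln for r in truth.per_cell_truth
                         for ln in r.fiber_lengths]
        assert len(lengths) == len(truth_lengths)
        for ln, tl in zip(sorted(lengths), sorted(truth_lengths)):
            assert ln == pytest.approx(tl, abs=3.0)


class TestMeasureCells:
    def test_moment_axis_ratio_of_analytic_ellipse(self):
        """A 40x20 axis ellipse has minor/major ratio 0.5 +/- 0.02."""
        nuclei = np.zeros((128, 128), dtype=np.int32)
        rr, cc = draw_ellipse(64, 64, 10, 20)  # semi-axes 10 and 20
        nuclei[rr, cc] = 1
        cells = np.zeros_like(nuclei)
        rr, cc = draw_disk((64, 64), 30)
        cells[rr, cc] = 1
        img = CellImage(channels={
            "dna": (nuclei > 0) * 200.0,
            "actin": (cells > 0) * 60.0,
            "protein": np.full(nuclei.shape, 7.0),
        })
        (rec,) = measure_cells(img, nuclei, cells)
        assert rec.eccentricity_ratio == pytest.approx(0.5, abs=0.02)
        assert rec.mean_nuc_intensity == pytest.approx(7.0)
        assert rec.mean_cyto_intensity == pytest.approx(7.0)

    def test_border_cells_excluded(self):
        nuclei = np.zeros((128, 128), dtype=np.int32)
        cells = np.zeros_like(nuclei)
        rr, cc = draw_disk((10, 64), 8, shape=cells.shape)
        nuclei[rr, cc] = 1
        rr, cc = draw_disk((10, 64), 20, shape=cells.shape)
        cells[rr, cc] = 1  # touches row 0
        img = CellImage(channels={
            "dna": (nuclei > 0) * 200.0, "actin": (cells > 0) * 60.0,
            "protein": np.ones(cells.shape),
        })
        assert measure_cells(img, nuclei, cells) == []

    def test_empty_cytoplasm_is_flagged(self):
        nuclei = np.zeros((128, 128), dtype=np.int32)
        rr, cc = draw_disk((64, 64), 10)
        nuclei[rr, cc] = 1
        cells = nuclei.copy()  # cell collapses to nucleus
        img = CellImage(channels={
            "dna": (nuclei > 0) * 200.0, "actin": (cells > 0) * 60.0,
            "protein": np.ones(cells.shape),
        })
        (rec,) = measure_cells(img, nuclei, cells)
        assert "empty_cytoplasm" in rec.flags
        assert np.isnan(rec.mean_cyto_intensity)

    def test_constant_offset_shifts_intensities_exactly(self, clean_field):
        image, truth = clean_field
        shifted = CellImage(channels={
            "dna": image.channels["dna"],
            "actin": image.channels["actin"],
            "protein": image.channels["protein"] + 11.5,
        })
        base = measure_cells(image, truth.nuclei_mask, truth.cell_mask)
        moved = measure_cells(shifted, truth.nuclei_mask, truth.cell_mask)
        for a, b in zip(base, moved):
            assert b.mean_nuc_intensity - a.mean_nuc_intensity == pytest.approx(11.5)
            assert b.mean_cyto_intensity - a.mean_cyto_intensity == pytest.approx(11.5)

    def test_scale_covariance_of_shape_metrics(self, clean_field):
        """2x upsampling preserves ratios and doubles displacement."""
        image, truth = clean_field
        up = lambda a: np.kron(a, np.ones((2, 2), dtype=a.dtype))  # noqa: E731
        big = CellImage(channels={c: up(a) for c, a in image.channels.items()})
        base = measure_cells(image, truth.nuclei_mask, truth.cell_mask)
        scaled = measure_cells(big, up(truth.nuclei_mask), up(truth.cell_mask))
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert b.eccentricity_ratio == pytest.approx(
                a.eccentricity_ratio, rel=0.02)
            assert b.nc_area_ratio == pytest.approx(a.nc_area_ratio, rel=0.02)
            if a.nuclear_displacement > 0.5:
                assert b.nuclear_displacement == pytest.approx(
                    2 * a.nuclear_displacement, rel=0.05)

    def test_metric_bounds_hold_for_every_record(self, noisy_field):
        image, _ = noisy_field
        nuclei = segment_nuclei(image)
        cells = segment_cells(image, nuclei)
        fibers = segment_stress_fibers(image, cells)
        for rec in measure_cells(image, nuclei, cells, fibers):
            assert 0 < rec.eccentricity_ratio <= 1
            assert 0 < rec.solidity <= 1
            assert 0 <= rec.pct_fiber_area <= 100
            assert 0 < rec.nc_area_ratio < 1
            assert rec.nuclear_displacement >= 0


class TestEstimateEffect:
    def _records(self, values):
        return [
            imaging.CellRecord(
                cell_id=i, nuclear_area=1, cell_area=2, eccentricity_ratio=1,
                solidity=1, nc_area_ratio=0.5, nuclear_displacement=v,
                pct_fiber_area=0, mean_nuc_intensity=v, mean_cyto_intensity=1,
            )
            for i, v in enumerate(values)
        ]

    def test_identical_groups_show_no_effect(self):
        grp = self._records([1.0, 2.0, 3.0, 4.0])
        eff = estimate_effect(grp, grp, "mean_nuc_intensity")
        assert eff.percent_change == 0.0
        assert eff.p_value > 0.9

    def test_fully_separated_small_groups_exact_rank_p(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 0.1
        (2 of the 20 equally likely rank assignments are as extreme)."""
        eff = estimate_effect(
            self._records([1.0, 2.0, 3.0]), self._records([4.0, 5.0, 6.0]),
            "mean_nuc_intensity",
        )
        assert eff.p_value == pytest.approx(0.1)
        assert eff.percent_change == pytest.approx(150.0)

    def test_unknown_metric_lists_valid_names(self):
        grp = self._records([1.0, 2.0])
        with pytest.raises(ValueError, match="nuclear_area"):
            estimate_effect(grp, grp, "no_such_metric")
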