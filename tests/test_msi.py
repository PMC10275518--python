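"""imzML round trip, window extraction, normalization, hemisphere ratios."""

import numpy as np
import pytest

from bbbq.errors import ExtractionError, MSIFormatError
from bbbq.imaging import RegionSet
from bbbq.msi import (
    IonImage,
    MSIDataset,
    extract_ion_image,
    hemisphere_intensity_ratio,
    ion_image_to_csv,
    normalize_ion_image,
    read_msi,
    render_ion_image,
    write_msi,
)
from bbbq.synthetic import SyntheticMSIConfig, make_msi_dataset


def _single_pixel(mzs, intensities, mz_range=(50.0, 700.0)):
    return MSIDataset(
        coordinates=[(1, 1)],
        spectra=[(np.asarray(mzs, dtype=float), np.asarray(intensities, dtype=float))],
        mz_range=mz_range,
    )


def _random_dataset(rng, n_pixels=6, n_peaks=40):
    coords = [(x + 1, y + 1) for y in range(2) for x in range(n_pixels // 2)]
    spectra = []
    for _ in coords:
        mz = np.sort(rng.uniform(50.0, 700.0, size=n_peaks))
        inten = rng.uniform(0.0, 100.0, size=n_peaks)
        spectra.append((mz, inten))
    return MSIDataset(coordinates=coords, spectra=spectra)


def naive_window_sum(dataset, target_mz, window_da):
    """Linear-scan oracle for window extraction."""
    nx, ny = dataset.grid_extent
    grid = np.full((ny, nx), np.nan)
    half = window_da / 2.0
    for (x, y), (mz, inten) in zip(dataset.coordinates, dataset.spectra):
        total = 0.0
        for m, v in zip(mz, inten):
            if target_mz - half <= m <= target_mz + half:
                total += v
        grid[y - 1, x - 1] = total
    return grid


class TestDatasetValidation:
    def test_duplicate_coordinates(self):
        with pytest.raises(MSIFormatError):
            MSIDataset(
                coordinates=[(1, 1), (1, 1)],
                spectra=[(np.array([100.0]), np.array([1.0]))] * 2,
            )

    def test_unsorted_mz(self):
        with pytest.raises(MSIFormatError):
            _single_pixel([200.0, 100.0], [1.0, 1.0])

    def test_negative_intensity(self):
        with pytest.raises(MSIFormatError):
            _single_pixel([100.0], [-1.0])

    def test_mz_outside_range(self):
        with pytest.raises(MSIFormatError):
            _single_pixel([10.0], [1.0])

    def test_empty_dataset(self):
        with pytest.raises(MSIFormatError):
            MSIDataset(coordinates=[], spectra=[])


class TestExtraction:
    def test_single_peak_at_target(self):
        ds = _single_pixel([217.0], [5.0])
        assert extract_ion_image(ds, 217.0).grid[0, 0] == 5.0

    def test_peak_outside_window(self):
        ds = _single_pixel([217.05], [5.0])
        assert extract_ion_image(ds, 217.0, 0.02).grid[0, 0] == 0.0

    def test_two_peaks_summed(self):
        ds = _single_pixel([216.995, 217.005], [2.0, 3.0])
        assert extract_ion_image(ds, 217.0, 0.02).grid[0, 0] == 5.0

    def test_closed_interval_endpoints(self):
        ds = _single_pixel([216.99, 217.01], [2.0, 3.0])
        assert extract_ion_image(ds, 217.0, 0.02).grid[0, 0] == 5.0

    def test_target_outside_range_errors(self):
        ds = _single_pixel([217.0], [5.0])
        with pytest.raises(ExtractionError):
            extract_ion_image(ds, 1000.0)

    def test_missing_grid_positions_are_nan(self):
        ds = MSIDataset(
            coordinates=[(1, 1), (2, 2)],
            spectra=[(np.array([100.0]), np.array([1.0]))] * 2,
        )
        grid = extract_ion_image(ds, 100.0).grid
        assert grid.shape == (2, 2)
        assert np.isnan(grid[0, 1]) and np.isnan(grid[1, 0])
        assert grid[0, 0] == 1.0 and grid[1, 1] == 1.0

    def test_oracle_equivalence_100_random_datasets(self):
        """Binary-search extraction equals the naive linear scan exactly."""
        rng = np.random.default_rng(1234)
        for _ in range(100):
            ds = _random_dataset(rng)
            target = rng.uniform(60.0, 690.0)
            window = rng.uniform(0.005, 5.0)
            got = extract_ion_image(ds, target, window).grid
            want = naive_window_sum(ds, target, window)
            assert np.array_equal(got, want)

    def test_linearity(self):
        rng = np.random.default_rng(7)
        ds = _random_dataset(rng)
        scaled = MSIDataset(
            coordinates=ds.coordinates,
            spectra=[(mz, 3.0 * inten) for mz, inten in ds.spectra],
        )
        a = extract_ion_image(ds, 300.0, 1.0).grid
        b = extract_ion_image(scaled, 300.0, 1.0).grid
        assert np.allclose(b, 3.0 * a)

    def test_window_monotonicity(self):
        rng = np.random.default_rng(8)
        ds = _random_dataset(rng)
        prev = extract_ion_image(ds, 350.0, 0.01).grid
        for w in (0.1, 1.0, 10.0, 100.0):
            cur = extract_ion_image(ds, 350.0, w).grid
            assert np.all(cur >= prev)
            prev = cur


class TestImzmlRoundTrip:
    def test_round_trip_float32(self, tmp_path):
        cfg = SyntheticMSIConfig(seed=3, grid_nx=6, grid_ny=4,
                                 n_background_peaks=10)
        ds, _, _ = make_msi_dataset(cfg)
        path = tmp_path / "phantom.imzML"
        write_msi(ds, path)
        back = read_msi(path)
        assert back.coordinates == ds.coordinates
        for (m1, i1), (m2, i2) in zip(ds.spectra, back.spectra):
            assert np.allclose(m2, m1, rtol=1e-6, atol=1e-4)
            assert np.allclose(i2, i1, rtol=1e-6)
            assert np.array_equal(m2, np.asarray(m1, dtype=np.float32))

    def test_pixel_size_supplied_on_read(self, tmp_path):
        # imzML files written here carry no physical pixel size; the
        # reader takes it as an argument instead.
        cfg = SyntheticMSIConfig(seed=3, grid_nx=4, grid_ny=4, pixel_size_um=50.0)
        ds, _, _ = make_msi_dataset(cfg)
        write_msi(ds, tmp_path / "p.imzML")
        assert read_msi(tmp_path / "p.imzML", pixel_size_um=50.0).pixel_size_um == 50.0

    def test_missing_ibd_errors(self, tmp_path):
        cfg = SyntheticMSIConfig(seed=3, grid_nx=4, grid_ny=4)
        ds, _, _ = make_msi_dataset(cfg)
        write_msi(ds, tmp_path / "p.imzML")
        (tmp_path / "p.ibd").unlink()
        with pytest.raises(MSIFormatError):
            read_msi(tmp_path / "p.imzML")


class TestNormalization:
    def test_none_is_identity(self):
        ds = _single_pixel([100.0, 217.0], [90.0, 10.0])
        img = extract_ion_image(ds, 217.0)
        assert normalize_ion_image(img, ds, "none") is img

    def test_tic(self):
        ds = _single_pixel([100.0, 217.0], [90.0, 10.0])
        img = normalize_ion_image(extract_ion_image(ds, 217.0), ds, "tic")
        assert img.grid[0, 0] == pytest.approx(0.1)

    def test_lockmass(self):
        ds = _single_pixel([217.0, 556.2771], [10.0, 2.0])
        img = normalize_ion_image(
            extract_ion_image(ds, 217.0), ds, "lockmass", lock_mz=556.2771
        )
        assert img.grid[0, 0] == pytest.approx(5.0)

    def test_lockmass_missing_peak_counts(self):
        ds = MSIDataset(
            coordinates=[(1, 1), (2, 1)],
            spectra=[
                (np.array([217.0, 556.2771]), np.array([10.0, 2.0])),
                (np.array([217.0]), np.array([10.0])),
            ],
        )
        img = normalize_ion_image(
            extract_ion_image(ds, 217.0), ds, "lockmass", lock_mz=556.2771
        )
        assert img.grid[0, 0] == pytest.approx(5.0)
        assert np.isnan(img.grid[0, 1])
        assert img.n_missing_normalized == 1


def _halves_regions(ny, nx):
    xs = np.arange(nx)
    tissue = np.ones((ny, nx), dtype=bool)
    return RegionSet(
        tissue=tissue,
        ipsilateral=tissue & (xs[None, :] >= nx - nx // 2),
        contralateral=tissue & (xs[None, :] < nx // 2),
        provenance="midline_split",
    )


class TestHemisphereRatio:
    def test_symmetric_is_one(self):
        img = IonImage(grid=np.full((4, 6), 7.0), target_mz=217.0)
        assert hemisphere_intensity_ratio(img, _halves_regions(4, 6)).ratio == 1.0

    def test_planted_five(self):
        grid = np.hstack([np.full((4, 3), 20.0), np.full((4, 3), 100.0)])
        img = IonImage(grid=grid, target_mz=217.0)
        hr = hemisphere_intensity_ratio(img, _halves_regions(4, 6))
        assert hr.ratio == 5.0
        assert (hr.ipsi_mean, hr.contra_mean) == (100.0, 20.0)

    def test_missing_pixels_excluded(self):
        grid = np.hstack([np.full((2, 2), 10.0), np.full((2, 2), 30.0)])
        grid[0, 0] = np.nan
        img = IonImage(grid=grid, target_mz=100.0)
        hr = hemisphere_intensity_ratio(img, _halves_regions(2, 4))
        assert hr.n_contra == 3
        assert hr.ratio == 3.0

    def test_noisy_recovery_within_5_percent(self, noisy_msi_phantom):
        """Planted 5x asymmetry recovered through the full extraction path."""
        cfg, (ds, regions, truth) = noisy_msi_phantom
        img = extract_ion_image(ds, cfg.drug_mz, 0.02)
        hr = hemisphere_intensity_ratio(img, regions)
        assert hr.ratio == pytest.approx(truth.ratio, rel=0.05)

    def test_swap_inverts_ratio(self, noisy_msi_phantom):
        cfg, (ds, regions, _) = noisy_msi_phantom
        img = extract_ion_image(ds, cfg.drug_mz)
        fwd = hemisphere_intensity_ratio(img, regions)
        swapped = RegionSet(
            tissue=regions.tissue,
            ipsilateral=regions.contralateral,
            contralateral=regions.ipsilateral,
            provenance=regions.provenance,
        )
        rev = hemisphere_intensity_ratio(img, swapped)
        assert rev.ratio == pytest.approx(1.0 / fwd.ratio)


class TestRendering:
    def test_heat_map_written(self, tmp_path):
        img = IonImage(grid=np.arange(4.0).reshape(2, 2), target_mz=217.0)
        render_ion_image(img, tmp_path / "im.png")
        assert (tmp_path / "im.png").stat().st_size > 0

    def test_all_zero_renders(self, tmp_path):
        img = IonImage(grid=np.zeros((3, 3)), target_mz=100.0)
        render_ion_image(img, tmp_path / "zero.png")
        assert (tmp_path / "zero.png").exists()

    def test_missing_rendered_distinct_from_zero(self, tmp_path):
        grid = np.zeros((2, 2))
        grid[0, 0] = np.nan
        render_ion_image(IonImage(grid=grid, target_mz=100.0), tmp_path / "m.png")
        from PIL import Image

        px = np.asarray(Image.open(tmp_path / "m.png").convert("RGB"))
        # the figure must contain both the NaN gray and the zero colormap color
        assert (px == [178, 178, 178]).all(axis=-1).any()

    def test_csv_matrix(self, tmp_path):
        grid = np.array([[1.0, np.nan], [2.5, 0.0]])
        ion_image_to_csv(IonImage(grid=grid, target_mz=100.0), tmp_path / "g.csv")
        back = np.genfromtxt(tmp_path / "g.csv", delimiter=",")
        assert np.allclose(back, grid, equal_nan=True)
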