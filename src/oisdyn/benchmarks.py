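"""Recovery benchmarks run on synthetic ground truth.

Each function builds its own scenario at the study's default acquisition
protocol (200 frames @ 10 Hz, 5-s stimulus at 5 s, 8 trials), injects known
effects and measures how well the analysis chain recovers them. They back
both the acceptance test-suite and ``scripts/acceptance.py``.

Field sizes per benchmark (documented in docs/methods.md): amplitude/timing
recovery at the native-like 128 px; dilation recovery at 256 px so a 2%
width change moves O(100) pixels and count quantization stays well below
the comparison tolerance; cohort replicates at 48 px so hundreds of animals
render in minutes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from . import dynamics, pipeline, regions, segmentation, stats
from . import synthetic as syn
from .io import OISMovie

__all__ = [
    "sd_map_oracle_max_error",
    "region_partition_violations",
    "amplitude_timing_recovery",
    "dilation_recovery",
    "segmentation_benchmark",
    "label_shuffle_control",
    "cohort_discrimination",
    "group_means_benchmark",
    "vascular_group_benchmark",
]


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31 - 1))


def sd_map_oracle_max_error(n_stacks: int = 20, seed: int = 0) -> float:
    """Max |vectorized SD map - per-pixel brute-force loop| over random stacks."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_stacks):
        frames = rng.uniform(0.0, 100.0, size=(50, 20, 20))
        movie = OISMovie(frames, 10.0, 0.05, 2.0, 1.0, 20)
        sd = regions.compute_sd_map(movie).sd
        for i in range(20):
            for j in range(20):
                p = frames[:, i, j]
                pa = p.mean()
                ref = np.sqrt(((p - pa) ** 2).mean())
                worst = max(worst, abs(sd[i, j] - ref))
    return worst


def region_partition_violations(n_pairs: int = 100, seed: int = 0) -> int:
    """Count of boolean partition-identity violations over random mask pairs."""
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_pairs):
        responsive = rng.random((16, 16)) > 0.5
        prob = rng.uniform(size=(16, 16))
        vessel = prob > 0.6
        pm = segmentation.VesselProbabilityMap(prob, segmentation.feature_names())
        m = regions.decompose_regions(responsive, pm)
        ok = (
            not (m.responsive_pial_artery & m.responsive_tissue).any()
            and np.array_equal(m.responsive_pial_artery | m.responsive_tissue, m.responsive_area)
            and not (m.nonresponsive_vessels & m.responsive_area).any()
            and np.array_equal(m.responsive_pial_artery, vessel & responsive)
            and np.array_equal(m.nonresponsive_vessels, vessel & ~responsive)
        )
        violations += not ok
    return violations


def _recovery_params(seed: int) -> syn.ScenarioParams:
    # scalar CBV recovery isolates the parenchymal response: dilation off so
    # the 7x7 ROI reads the injected amplitude, not artery-edge artifacts
    return dataclasses.replace(
        syn.CONTROL_PARAMS, time_to_peak_s=4.6, dilation_pct=0.0, rng_seed=seed
    )


def amplitude_timing_recovery(
    amplitudes=(1.0, 2.0, 4.0, 6.0), n_runs: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Measured max dCBV and time-to-peak for injected amplitudes.

    128x128 datasets, 8 trials, white noise SD 0.2% and default
    physiological oscillations; injected time-to-peak 4.6 s.
    """
    rows = []
    for amp in amplitudes:
        for run in range(n_runs):
            p = dataclasses.replace(
                _recovery_params(_sub_seed(seed, 1000 + run)), peak_amplitude_pct=amp
            )
            truth = syn.generate_vessel_tree(p)
            res = pipeline.analyze_cbv(syn.render_trials(p, truth))
            rows.append(
                {
                    "amplitude_pct": amp,
                    "run": run,
                    "measured_pct": res.metrics.max_change_pct,
                    "measured_ttp_s": res.metrics.time_to_peak_s,
                }
            )
    return pd.DataFrame(rows)


def dilation_recovery(
    dilations=(2.0, 5.0, 10.0, 20.0), size: int = 256, seed: int = 0
) -> pd.DataFrame:
    """Noiseless dilation sweep: measured pixel-count change vs. the
    rasterization oracle evaluated on the ground-truth centerlines."""
    rows = []
    for d in dilations:
        p = dataclasses.replace(
            syn.CONTROL_PARAMS, image_height_px=size, image_width_px=size,
            dilation_pct=d, peak_amplitude_pct=0.0, noise_sd_pct=0.0,
            osc_components=(), n_trials=1, rng_seed=_sub_seed(seed, 2000),
        )
        truth = syn.generate_vessel_tree(p)
        movie = pipeline.preprocess_trials(syn.render_trials(p, truth))
        region = truth.norm_dist_dilating <= 1.0
        static = truth.norm_dist_static <= 1.0
        trace = dynamics.dilation_trace(movie, region, exclude=static)
        measured = dynamics.peak_metrics(trace).max_change_pct

        nbhd = ndimage.binary_dilation(region, structure=disk(3))
        nbhd &= ~ndimage.binary_dilation(static, structure=disk(1))
        peak_scale = truth.dilation_profile.max()
        c0 = (truth.vessel_mask & nbhd).sum()
        c1 = (truth.vessel_mask_at(peak_scale) & nbhd).sum()
        rows.append(
            {
                "dilation_pct": d,
                "measured_pct": measured,
                "oracle_pct": 100.0 * (c1 / c0 - 1.0),
            }
        )
    return pd.DataFrame(rows)


def segmentation_benchmark(n_scenes: int = 20, seed: int = 0) -> pd.DataFrame:
    """IoU of the trained classifier (threshold 0.6) vs. ground truth on
    seeded scenes with noise at 1% of the vessel/tissue dynamic range."""
    rows = []
    for s in range(n_scenes):
        p = dataclasses.replace(syn.CONTROL_PARAMS, rng_seed=_sub_seed(seed, 3000 + s))
        truth = syn.generate_vessel_tree(p)
        noise = 0.01 * p.vessel_contrast * p.baseline_counts
        img = syn.render_reference_image(p, truth, noise_sd_counts=noise)
        prob = pipeline.segment_from_truth(img, truth.vessel_mask, rng_seed=s)
        pred = segmentation.threshold_vessels(prob, 0.6)
        gt = truth.vessel_mask
        rows.append({"scene": s, "iou": (pred & gt).sum() / (pred | gt).sum()})
    return pd.DataFrame(rows)


def label_shuffle_control(
    n_scenes: int = 3, n_permutations: int = 5, seed: int = 0
) -> list[float]:
    """Balanced held-out accuracy after shuffling the training labels.

    A sound classifier collapses to chance. A *single* permutation retains
    a random residual label/class correlation of order 1/sqrt(n_labels)
    which separable features amplify, so several permutations per scene are
    averaged before comparing against 0.5.
    """
    accs = []
    for s in range(n_scenes):
        p = dataclasses.replace(syn.CONTROL_PARAMS, rng_seed=_sub_seed(seed, 4000 + s))
        truth = syn.generate_vessel_tree(p)
        noise = 0.01 * p.vessel_contrast * p.baseline_counts
        img = syn.render_reference_image(p, truth, noise_sd_counts=noise)
        rng = np.random.default_rng(_sub_seed(seed, 4100 + s))
        feats = segmentation.extract_pixel_features(img)
        X = feats.reshape(-1, feats.shape[-1])
        train = segmentation.auto_scribbles(truth.vessel_mask, n_per_class=400, rng=rng)
        idx = np.flatnonzero(train.labels)
        # evaluate on every core pixel not used for training (balanced over
        # the two classes) so the estimate of chance level is tight
        core = segmentation.auto_scribbles(
            truth.vessel_mask, n_per_class=10**9, rng=rng
        ).labels
        core.flat[idx] = segmentation.UNLABELED
        hidx = np.flatnonzero(core)
        y = core.flat[hidx]
        for perm in range(n_permutations):
            shuffled = train.labels.copy()
            shuffled.flat[idx] = rng.permutation(shuffled.flat[idx])
            clf = segmentation.train_classifier(feats, shuffled, rng_seed=perm)
            pred = clf.model.predict(X[hidx])
            acc = float(
                ((pred == y)[y == segmentation.VESSEL].mean()
                 + (pred == y)[y == segmentation.TISSUE].mean()) / 2.0
            )
            accs.append(acc)
    return accs


def _cohort_scenarios() -> tuple[syn.ScenarioParams, syn.ScenarioParams]:
    control = dataclasses.replace(
        syn.CONTROL_PARAMS, image_height_px=48, image_width_px=48,
        pixel_size_mm=0.07, dilation_pct=0.0,
    )
    stress = dataclasses.replace(
        control,
        peak_amplitude_pct=syn.STRESS_PARAMS.peak_amplitude_pct,
        time_to_peak_s=syn.STRESS_PARAMS.time_to_peak_s,
    )
    return control, stress


def cohort_discrimination(
    n_cohorts: int = 100, n_per_group: int = 10, seed: int = 0, null: bool = False
) -> pd.DataFrame:
    """Mann-Whitney p on measured max dCBV for replicate synthetic cohorts.

    With ``null=True`` both groups are drawn from the control generator, so
    the rejection rate estimates the empirical type-I error.
    """
    control, stress = _cohort_scenarios()
    stress_sds = None
    if null:
        # identical generators: same scenario AND same between-animal SDs
        stress = control
        stress_sds = syn.CONTROL_BETWEEN_ANIMAL_SD
    rows = []
    for c in range(n_cohorts):
        cohort = syn.generate_cohort(
            control, stress, n_per_group=n_per_group,
            rng_seed=_sub_seed(seed, (6000 if null else 5000) + c),
            stress_sds=stress_sds,
        )
        df = pipeline.cohort_cbv_table(cohort)
        a = df[df.group == "control"].max_cbv_pct.to_numpy()
        b = df[df.group == "stress"].max_cbv_pct.to_numpy()
        res = stats.compare_groups(a, b)
        rows.append({"cohort": c, "p_value": res.p_value,
                     "mean_control": a.mean(), "mean_stress": b.mean()})
    return pd.DataFrame(rows)


def group_means_benchmark(n_per_group: int = 10, seed: int = 0) -> pd.DataFrame:
    """One cohort at 64x64: per-group mean measured max dCBV and TTP."""
    control, stress = _cohort_scenarios()
    control = dataclasses.replace(control, image_height_px=64, image_width_px=64,
                                  pixel_size_mm=0.06)
    stress = dataclasses.replace(stress, image_height_px=64, image_width_px=64,
                                 pixel_size_mm=0.06)
    cohort = syn.generate_cohort(control, stress, n_per_group=n_per_group,
                                 rng_seed=_sub_seed(seed, 7000))
    return pipeline.cohort_cbv_table(cohort)


def vascular_group_benchmark(
    seed: int = 0, n_control: int = 6, n_stress: int = 5
) -> pd.DataFrame:
    """Per-animal vascular-chain results for a small two-group cohort.

    Group sizes default to 6 control / 5 stress animals (the usable group
    sizes of the dilation comparison). Each animal runs the full chain:
    segmentation, SD-map regions, pixel-count dilation metrics; per-animal
    geometry makes the dilation estimate scatter widely, which is why group
    means, not single animals, are reported downstream.
    """
    rows = []
    for name, base, n in (
        ("control", syn.CONTROL_PARAMS, n_control),
        ("stress", syn.STRESS_PARAMS, n_stress),
    ):
        for a in range(n):
            p = dataclasses.replace(base, rng_seed=_sub_seed(seed, 8000 + 10 * a))
            truth = syn.generate_vessel_tree(p)
            trials = syn.render_trials(p, truth)
            res = pipeline.analyze_vascular(
                trials, truth=truth, rng_seed=_sub_seed(seed, 8001 + 10 * a)
            )
            m = res.dilation_metrics
            rows.append(
                {
                    "group": name,
                    "animal": a,
                    "injected_dilation_pct": p.dilation_pct,
                    "max_dilation_pct": m.max_change_pct,
                    "time_to_peak_s": m.time_to_peak_s,
                    "onset_s": m.onset_time_s,
                    "rising_slope_pct_per_s": m.rising_slope_pct_per_s,
                    "nonresponsive_dilation_pct": (
                        res.nonresponsive_metrics.max_change_pct
                        if res.nonresponsive_metrics else np.nan
                    ),
                    "vessel_iou": res.vessel_iou,
                }
            )
    return pd.DataFrame(rows)
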