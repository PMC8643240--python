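"""End-to-end orchestration: simulate -> train -> segment -> evaluate -> tabulate.

The demo pipeline mirrors a reader study on the synthetic cohort: every case
is segmented, called cancer or hyperplasia by a lesion-presence heuristic,
and the resulting detection counts and risk strata are compared against the
cohort's ground truth with the concordance statistics.

The cancer call is a deliberately simple image heuristic, not a learned
classifier: a case is called positive when the (CNN or naive) gland
segmentation contains a sufficiently large enclosed low-signal defect —
lesions sit inside the gland and are labelled as non-gland by the three-class
network, so they appear as holes.  The "routine reading" arm applies the same
hole test to a plain intensity threshold of the raw noisy image, emulating
segmentation without the network.

Per-stage seeds are fanned out from the master seed by stable hashing of the
stage name, so each stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from prostseg import concordance as conc
from prostseg import io_utils, phantoms, pssnet, risk_strat, seg_metrics

__all__ = [
    "stage_seed",
    "detect_lesion_defect",
    "naive_threshold_segmentation",
    "segmentation_benchmark",
    "run_demo",
]


def segmentation_benchmark(
    seed: int,
    n_train: int = 200,
    n_eval: int = 50,
    epochs: int = 10,
    params: phantoms.PhantomParams | None = None,
) -> dict:
    """Train the default network and score it on held-out phantoms.

    Generates ``n_train + n_eval`` phantoms from the master ``seed``, trains
    the default configuration for ``epochs`` epochs on the first ``n_train``,
    and returns the per-case and mean foreground Dice and Hausdorff metrics
    on the remainder.
    """
    if params is None:
        params = phantoms.PhantomParams()
    seeds = np.random.SeedSequence(seed).spawn(n_train + n_eval)
    data = [phantoms.generate_phantom(params, s) for s in seeds]
    config = pssnet.NetworkConfig(
        input_size=params.image_height, epochs=epochs, seed=seed
    )
    model, log = pssnet.train_pssnet(data[:n_train], config)
    results = [
        seg_metrics.evaluate_segmentation(pssnet.segment(model, im)[0], mk)
        for im, mk in data[n_train:]
    ]
    return {
        "mean_dsc": float(np.mean([r.dsc for r in results])),
        "mean_hd": float(np.mean([r.hd for r in results])),
        "per_case": results,
        "training_log": log,
        "model": model,
    }


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _disk(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


def detect_lesion_defect(mask: np.ndarray, min_pixels: int = 10, close_radius: int = 4) -> bool:
    """Call a case positive if the gland segmentation has a low-signal defect.

    ``mask`` is a {0,1,2} label mask.  A lesion is labelled background by the
    three-class network but sits inside (or bites into) the gland, so the
    defect is recovered as the background pixels inside the morphological
    closing of the gland foreground (closing bridges defects that break the
    gland outline; hole-filling catches fully enclosed ones).
    """
    fg = np.asarray(mask) > 0
    hull = ndimage.binary_fill_holes(ndimage.binary_closing(fg, structure=_disk(close_radius)))
    defect = hull & ~fg
    return int(defect.sum()) >= min_pixels


def naive_threshold_segmentation(
    image: np.ndarray, threshold: float = 115.0, median_size: int = 3
) -> np.ndarray:
    """Segment the gland by plain intensity thresholding of the raw image.

    A median filter suppresses single-pixel noise before thresholding; the
    result stands in for a routine (non-CNN) reading in the demo pipeline.
    Returns a {0, 2} mask (no central/marginal distinction).
    """
    smoothed = ndimage.median_filter(np.asarray(image, dtype=np.float64), size=median_size)
    return np.where(smoothed > threshold, 2, 0).astype(np.uint8)


def run_demo(
    out_dir,
    seed: int,
    n_train: int = 32,
    n_cancer: int = 10,
    n_hyperplasia: int = 12,
    epochs: int = 25,
    params: phantoms.PhantomParams | None = None,
    defect_min_pixels: int = 10,
) -> dict:
    """Run the full pipeline at demonstration scale and write all artifacts.

    Writes, under ``out_dir``: the cohort records (``records.csv``),
    per-case segmentation metrics (``metrics.csv``), the detection table
    (``detections.csv``), risk strata (``strata.csv``), the concordance
    report (``report.csv``), a model checkpoint and a manifest.  Returns the
    in-memory results.  Everything derives from ``seed``; two runs with the
    same seed produce byte-identical CSV outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = phantoms.PhantomParams()

    # --- train on lesion-free phantoms -----------------------------------
    train_seed = stage_seed(seed, "train")
    train_set = [
        phantoms.generate_phantom(params, stage_seed(train_seed, f"phantom{i}"))
        for i in range(n_train)
    ]
    config = pssnet.NetworkConfig(
        input_size=params.image_height, epochs=epochs, seed=train_seed
    )
    model, log = pssnet.train_pssnet(train_set, config)
    pssnet.save_model(model, out / "model.ckpt.npz")

    # --- simulate the clinical cohort ------------------------------------
    cohort = phantoms.generate_cohort(
        n_cancer, n_hyperplasia, params, seed=stage_seed(seed, "cohort")
    )
    io_utils.save_records([c.record for c in cohort], out / "records.csv")

    # --- segment, score, classify -----------------------------------------
    metric_rows = []
    detections = {"pathology": [0, 0], "mri_before": [0, 0], "mri_after": [0, 0]}
    strata: dict[str, dict[str, int]] = {
        m: {g: 0 for g in risk_strat.RISK_GROUPS} for m in detections
    }
    rule = risk_strat.RiskRule()
    for case in cohort:
        pred, _ = pssnet.segment(model, case.image)
        m = seg_metrics.evaluate_segmentation(pred, case.mask, mode="foreground")
        metric_rows.append(
            {
                "case_id": case.record.case_id,
                "dsc": m.dsc,
                "hd": m.hd,
                "hd_forward": m.hd_forward,
                "hd_backward": m.hd_backward,
            }
        )

        truth_cancer = case.record.true_class == "cancer"
        naive_call = detect_lesion_defect(
            naive_threshold_segmentation(case.image), defect_min_pixels
        )
        cnn_call = detect_lesion_defect(pred, defect_min_pixels)
        for method, call in (
            ("pathology", truth_cancer),
            ("mri_before", naive_call),
            ("mri_after", cnn_call),
        ):
            detections[method][0 if call else 1] += 1
            if call and truth_cancer:
                # risk grading applies to cases called AND confirmed cancer;
                # the demo grades with the true clinical record
                strata[method][risk_strat.assign_risk(case.record, rule)] += 1

    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(out / "metrics.csv", index=False, float_format="%.6f")

    det_df = pd.DataFrame(
        [
            {"method": m, "n_cancer": c, "n_hyperplasia": h}
            for m, (c, h) in detections.items()
        ]
    )
    det_df.to_csv(out / "detections.csv", index=False)
    strata_df = pd.DataFrame(
        [{"method": m, **counts} for m, counts in strata.items()]
    )
    strata_df.to_csv(out / "strata.csv", index=False)

    report = conc.concordance_report(det_df, strata_df)
    report.to_csv(out / "report.csv", index=False, float_format="%.6f")

    io_utils.write_manifest(
        out / "manifest.json",
        {
            "n_train": n_train,
            "n_cancer": n_cancer,
            "n_hyperplasia": n_hyperplasia,
            "epochs": epochs,
            "phantom": params.__dict__ | {"intensity_means": dict(params.intensity_means)},
            "network": config.__dict__,
            "defect_min_pixels": defect_min_pixels,
        },
        seed,
    )
    return {
        "training_log": log,
        "metrics": metrics_df,
        "detections": det_df,
        "strata": strata_df,
        "report": report,
    }
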