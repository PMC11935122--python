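"""Top-level pipeline: simulate -> rescale -> QC -> hallucination -> structure.

One config, one seed, one output directory; re-running with the same
config and seed reproduces every numeric output byte-identically.  The
rescale fit sees only training pairs — test frames are generated from a
separate phantom and never enter the fit (asserted at run time).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hallucination import adjacent_frame_ssim, classify_pixels, hallucination_report
from .io import StackMeta, write_stack
from .metrics import qc_report
from .phantom import (AcquisitionParams, DynamicsParams, PhantomParams,
                      GROUND_TRUTH_ACQUISITION, LOW_INTENSITY_ACQUISITION,
                      generate_phantom, simulate_acquisition, simulate_dark_movie,
                      simulate_prediction, simulate_timeseries)
from .rescale import apply_rescale, fit_rescale, save_rescale_params
from .structure import (rolling_ball_subtract, segment_er, summaries_to_frame,
                        summarize_timeseries)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated configuration for one end-to-end run."""

    out_dir: str = "stedqc_out"
    rng_seed: int = 0
    height_px: int = 256
    width_px: int = 256
    pixel_size_nm: float = 20.0
    frame_interval_s: float = 4.6
    n_frames: int = 20
    rearrangement_rate: float = 0.1
    n_train_pairs: int = 4
    n_seed_nodes: int = 40
    n_sheets: int = 3
    tube_width_nm: float = 100.0
    psf_fwhm_nm: float = 90.0
    dark_count_rate: float = 0.01
    rolling_ball_radius_px: int = 15
    rfrc_block_px: int = 64
    rfrc_stride_px: int = 16
    rfrc_background_intensity: float = 20.0
    stages: tuple[str, ...] = ("simulate", "rescale", "qc", "halluc", "structure")

    _KNOWN_STAGES = ("simulate", "rescale", "qc", "halluc", "structure")

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in self._KNOWN_STAGES:
                raise ConfigError(f"unknown stage: {s!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are a hard error."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)
             if not f.name.startswith("_")}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in doc:
        doc["stages"] = tuple(doc["stages"])
    try:
        return PipelineConfig(**doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _seeds(root: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(root).generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns a summary dict.

    Writes TIFF stacks, per-stage CSVs, the resolved config, and a run log
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump({**dataclasses.asdict(config),
                        "stages": list(config.stages)}, sort_keys=True))
    summary: dict = {"version": __version__, "rng_seed": config.rng_seed}
    meta = StackMeta(pixel_size_nm=config.pixel_size_nm,
                     frame_interval_s=config.frame_interval_s,
                     rng_seed=config.rng_seed)
    seeds = _seeds(config.rng_seed, 6 + 2 * config.n_train_pairs)

    phantom_kw = dict(height_px=config.height_px, width_px=config.width_px,
                      pixel_size_nm=config.pixel_size_nm,
                      n_seed_nodes=config.n_seed_nodes, n_sheets=config.n_sheets,
                      tube_width_nm=config.tube_width_nm)
    acq_high = dataclasses.replace(GROUND_TRUTH_ACQUISITION,
                                   psf_fwhm_nm=config.psf_fwhm_nm,
                                   dark_count_rate=config.dark_count_rate)

    train_preds, train_truths = [], []
    test_pred = test_truth = test_low = None
    pred_movie = truth_labels = None

    if "simulate" in config.stages:
        # training pairs: distinct phantoms, high-dose truth + emulated prediction
        for i in range(config.n_train_pairs):
            ph = generate_phantom(PhantomParams(rng_seed=seeds[i], **phantom_kw))
            acq = dataclasses.replace(acq_high, rng_seed=seeds[config.n_train_pairs + i])
            train_truths.append(simulate_acquisition(ph, acq))
            train_preds.append(simulate_prediction(
                ph, psf_fwhm_nm=config.psf_fwhm_nm,
                rng_seed=seeds[config.n_train_pairs + i]))
        # held-out test phantom, tagged so the fit can never see it
        k = 2 * config.n_train_pairs
        test_ph = generate_phantom(PhantomParams(rng_seed=seeds[k], **phantom_kw))
        test_truth = simulate_acquisition(
            test_ph, dataclasses.replace(acq_high, rng_seed=seeds[k + 1]))
        test_low = simulate_acquisition(
            test_ph, dataclasses.replace(LOW_INTENSITY_ACQUISITION,
                                         psf_fwhm_nm=config.psf_fwhm_nm,
                                         dark_count_rate=config.dark_count_rate,
                                         rng_seed=seeds[k + 2]))
        test_pred = simulate_prediction(test_ph, psf_fwhm_nm=config.psf_fwhm_nm,
                                        rng_seed=seeds[k + 3])
        # prediction movie of a remodelling phantom, with per-frame truth
        dyn = DynamicsParams(n_frames=config.n_frames,
                             frame_interval_s=config.frame_interval_s,
                             rearrangement_rate=config.rearrangement_rate,
                             rng_seed=seeds[k + 4])
        _, truth_labels = simulate_timeseries(
            PhantomParams(rng_seed=seeds[k], **phantom_kw), dyn,
            dataclasses.replace(LOW_INTENSITY_ACQUISITION,
                                psf_fwhm_nm=config.psf_fwhm_nm,
                                dark_count_rate=config.dark_count_rate,
                                rng_seed=seeds[k + 5]))
        # denoised movie emulation: blurred truth density per frame, normalized
        pred_movie = np.stack([
            simulate_prediction(
                dataclasses.replace(
                    generate_phantom(PhantomParams(rng_seed=seeds[k], **phantom_kw)),
                    density_map=(lab.labels > 0).astype(float), label_map=lab),
                psf_fwhm_nm=config.psf_fwhm_nm, rng_seed=seeds[k + 5] + t)
            for t, lab in enumerate(truth_labels)])
        write_stack(out / "test_truth.tif", test_truth.astype(np.uint16), meta)
        write_stack(out / "test_low.tif", test_low.astype(np.uint16), meta)
        write_stack(out / "test_pred.tif", test_pred.astype(np.float32), meta)
        write_stack(out / "pred_movie.tif", pred_movie.astype(np.float32), meta)
        summary["simulate"] = {"n_train_pairs": config.n_train_pairs,
                               "n_frames": config.n_frames}

    params = None
    if "rescale" in config.stages:
        if not train_preds:
            raise RuntimeError("rescale stage requires the simulate stage")
        # train/test separation: the fit consumes only the training lists
        assert test_pred is not None and not any(tp is test_pred for tp in train_preds)
        params = fit_rescale(train_preds, train_truths)
        save_rescale_params(params, out / "rescale_params.yaml")
        test_pred = apply_rescale(test_pred, params)
        pred_movie = np.stack([apply_rescale(f, params) for f in pred_movie])
        summary["rescale"] = {"scale": params.scale, "offset": params.offset,
                              "n_training_pixels": params.n_training_pixels}

    if "qc" in config.stages:
        report = qc_report(test_pred, test_truth, config.pixel_size_nm,
                           block_size_px=config.rfrc_block_px,
                           stride_px=config.rfrc_stride_px,
                           background_intensity=config.rfrc_background_intensity)
        df = pd.DataFrame([dataclasses.asdict(report)])
        df.to_csv(out / "qc_report.csv", index=False)
        summary["qc"] = dataclasses.asdict(report)

    if "halluc" in config.stages:
        conf = classify_pixels(np.asarray(test_low, dtype=np.int64))
        write_stack(out / "confidence_labels.tif", conf.labels, meta)
        dark = simulate_dark_movie((config.height_px, config.width_px),
                                   config.n_frames, config.dark_count_rate + 0.01,
                                   rng_seed=seeds[-1])
        dr = float(pred_movie.max() - pred_movie.min()) or 1.0
        rep = hallucination_report(pred_movie, dark, data_range=dr)
        pd.DataFrame({
            "transition": np.arange(rep.pred_trace.values.size),
            "pred_ssim": rep.pred_trace.values,
            "flagged": rep.flags.astype(int),
        }).to_csv(out / "hallucination_trace.csv", index=False)
        summary["halluc"] = {
            "pred_trace_mean": rep.pred_trace.mean,
            "dark_trace_mean": rep.dark_trace.mean,
            "n_flagged": rep.n_flagged,
            "background_fraction": conf.fraction(0),
            "signal_fraction": conf.fraction(2),
        }

    if "structure" in config.stages:
        labels = [segment_er(rolling_ball_subtract(f, config.rolling_ball_radius_px),
                             config.pixel_size_nm)
                  for f in pred_movie]
        summaries = summarize_timeseries(pred_movie, labels)
        df = summaries_to_frame(summaries)
        df.to_csv(out / "structure_summary.csv", index=False)
        hist: dict[int, int] = {}
        for s in summaries:
            for order, n in s.junction_order_counts.items():
                hist[order] = hist.get(order, 0) + n
        pd.DataFrame(sorted(hist.items()), columns=["junction_order", "count"]) \
            .to_csv(out / "junction_histogram.csv", index=False)
        summary["structure"] = {
            "mean_tube_fraction": float(np.nanmean(df["tube_fraction"])),
            "mean_sheet_fraction": float(np.nanmean(df["sheet_fraction"])),
            "modal_junction_order": max(hist, key=hist.get) if hist else None,
        }

    (out / "run_log.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    return summary
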