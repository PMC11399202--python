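"""End-to-end three-arm experiment on synthetic crossing-fiber phantoms.

Stages: design the 64-direction MPG scheme -> simulate phantoms -> split
the scheme (b0 + first 32 as network input, second 32 as teaching data) ->
train the 3D U-net -> predict the held-out second halves -> assemble the
evaluation arms

    (a) b0 + 32 measured volumes,
    (b) b0 + 32 measured + 32 predicted volumes,
    (c) b0 + 64 measured volumes (reference),

-> reconstruct DTI / QBI / GQI per arm -> compute SSIM, PSNR, JSD, ACC,
ROI FA/E1, tractography DSC -> paired statistics.  Every random choice
consumes a named seed derived from the master seed, so a config plus seed
reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import unet3d
from .dwi_io import DWIVolume, apply_normalization, compute_b0_mask, invert_normalization
from .gradients import GradientScheme, design_scheme, min_folded_angle_deg, split_scheme
from .metrics import (
    acc_fields,
    dice,
    jsd_fields,
    paired_compare,
    psnr_volume,
    ssim_volume,
)
from .phantom import PhantomCase, PhantomConfig, generate_dataset, make_roi_set
from .recon import find_peaks, fit_dti, gqi_sdf, qbi_odf, roi_statistics, sample_odf
from .sphere import default_sphere, n_sh_coeffs
from .tracking import TrackingParams, filter_by_rois, track, voxelize
from .unet3d import ModelConfig, TrainConfig

__all__ = ["ExperimentConfig", "run_experiment", "load_config"]

ARMS = ("a", "b", "c")
METHODS = ("qbi", "gqi")


@dataclasses.dataclass
class ExperimentConfig:
    """Desk-scale defaults: 32^3 grids, 20 training phantoms, a compact
    U-net (3 levels, 8 base filters), 40 epochs."""

    n_directions: int = 64
    bvalue: float = 3000.0
    split_k: int = 32
    scheme_restarts: int = 20
    scheme_iterations: int = 200
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    model: ModelConfig = dataclasses.field(
        default_factory=lambda: ModelConfig(levels=3, base_filters=8)
    )
    train: TrainConfig = dataclasses.field(
        default_factory=lambda: TrainConfig(
            minibatch_size=2, epochs=40, learning_rate=1e-2, lr_schedule="cosine"
        )
    )
    qbi_regularization: float = 0.006
    gqi_sampling_ratio: float = 1.25
    peak_relative_threshold: float = 0.5
    peak_min_separation: float = 25.0
    tracking: TrackingParams = dataclasses.field(default_factory=TrackingParams)
    mask_method: str = "otsu"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "phantom" in d:
            d["phantom"] = PhantomConfig(**_tuplify(d["phantom"]))
        if "model" in d:
            d["model"] = ModelConfig(**d["model"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        if "tracking" in d:
            d["tracking"] = TrackingParams(**d["tracking"])
        return cls(**d)


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path) -> ExperimentConfig:
    return ExperimentConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _seeds(master: int) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(4) % (2**31)
    return {
        "scheme": int(state[0]),
        "dataset": int(state[1]),
        "model": int(state[2]),
        "train": int(state[3]),
    }


def _split_indices(scheme: GradientScheme, first: GradientScheme, second: GradientScheme):
    pos = {lab: i for i, lab in enumerate(scheme.labels)}
    return [pos[l] for l in first.labels], [pos[l] for l in second.labels]


def _training_pairs(cases: list[PhantomCase], idx_first, idx_second):
    pairs = []
    for case in cases:
        vol = apply_normalization(case.volume)
        data = np.moveaxis(vol.data, -1, 0)
        pairs.append((data[idx_first], data[idx_second]))
    return pairs


def _first_half_volume(case: PhantomCase, first: GradientScheme, idx_first) -> DWIVolume:
    return DWIVolume(case.volume.data[..., idx_first], case.volume.affine, first)


def _reconstruct(arm_vol: DWIVolume, method: str, mask, cfg: ExperimentConfig):
    if method == "qbi":
        return qbi_odf(arm_vol, mask=mask, regularization=cfg.qbi_regularization)
    return gqi_sdf(arm_vol, mask=mask, sampling_ratio=cfg.gqi_sampling_ratio)


def _pad_sh(sh: np.ndarray, lmax_from: int, lmax_to: int) -> np.ndarray:
    """Zero-pad SH coefficient rows from one even order up to another,
    keeping (l, m) slots aligned."""
    if lmax_from == lmax_to:
        return sh
    out = np.zeros(sh.shape[:-1] + (n_sh_coeffs(lmax_to),))
    src = 0
    dst = 0
    for l in range(0, lmax_to + 1, 2):
        n = 2 * l + 1
        if l <= lmax_from:
            out[..., dst : dst + n] = sh[..., src : src + n]
            src += n
        dst += n
    return out


def _evaluate_case(
    case: PhantomCase,
    model,
    scheme: GradientScheme,
    first: GradientScheme,
    second: GradientScheme,
    idx_first,
    idx_second,
    cfg: ExperimentConfig,
) -> dict:
    vol = case.volume
    truth = case.truth
    norm_in = apply_normalization(
        DWIVolume(vol.data[..., idx_first], vol.affine, first)
    )
    predicted_norm = unet3d.predict_volume(model, norm_in, second)
    predicted = invert_normalization(predicted_norm)
    measured_second = DWIVolume(vol.data[..., idx_second], vol.affine, second)
    input_dwi = DWIVolume(vol.data[..., idx_first], vol.affine, first)
    arms = unet3d.assemble_arms(input_dwi, predicted, measured_second)

    mask = compute_b0_mask(arms["c"].b0(), method=cfg.mask_method).data

    # --- DWI similarity: per-MPG-axis SSIM / PSNR of prediction vs measured
    ssim_axes, psnr_axes = [], []
    for ch in range(predicted.data.shape[-1]):
        ssim_axes.append(
            ssim_volume(predicted.data[..., ch], measured_second.data[..., ch], mask)
        )
        psnr_axes.append(
            psnr_volume(predicted.data[..., ch], measured_second.data[..., ch], mask)
        )

    # --- DTI: FA / E1 ROI statistics per arm
    rois = {
        "bundle0": truth.bundle_masks[0] & ~truth.bundle_masks[1],
        "bundle1": truth.bundle_masks[1] & ~truth.bundle_masks[0],
        "crossing": truth.bundle_masks[0] & truth.bundle_masks[1],
        "background": truth.support_mask & ~truth.object_mask,
    }
    roi_stats: dict[str, dict] = {"fa": {}, "e1": {}}
    for arm in ARMS:
        tf = fit_dti(arms[arm], mask=mask)
        roi_list = list(rois.values())
        roi_stats["fa"][arm] = {
            name: s for name, s in zip(rois, roi_statistics(tf.fa, roi_list))
        }
        roi_stats["e1"][arm] = {
            name: s for name, s in zip(rois, roi_statistics(tf.e1, roi_list))
        }

    # --- diffusion profiles: voxelwise JSD / ACC of (a vs c) and (b vs c)
    sphere = default_sphere()
    profile: dict[str, dict] = {}
    odfs: dict[str, dict] = {}
    for method in METHODS:
        fields = {arm: _reconstruct(arms[arm], method, mask, cfg) for arm in ARMS}
        odfs[method] = fields
        samples = {arm: sample_odf(fields[arm], sphere)[0] for arm in ARMS}
        lmax_ref = fields["c"].lmax
        sh = {
            arm: _pad_sh(fields[arm].sh[mask], fields[arm].lmax, lmax_ref)
            for arm in ARMS
        }
        entry = {}
        for pair in (("a", "c"), ("b", "c")):
            j = jsd_fields(samples[pair[0]], samples[pair[1]])
            a = acc_fields(sh[pair[0]], sh[pair[1]])
            defined = ~np.isnan(a)
            entry[f"jsd_{pair[0]}c"] = float(np.mean(j))
            entry[f"acc_{pair[0]}c"] = float(np.mean(a[defined]))
            entry[f"n_voxels"] = int(j.size)
        profile[method] = entry

    # --- tractography: per-bundle DSC against arm (c)
    peak_kw = dict(
        relative_threshold=cfg.peak_relative_threshold,
        min_separation_angle=cfg.peak_min_separation,
    )
    tracking: dict[str, dict] = {}
    for method in METHODS:
        peaks = {arm: find_peaks(odfs[method][arm], sphere, **peak_kw) for arm in ARMS}
        entry = {}
        for b in range(truth.bundle_masks.shape[0]):
            rois_b = make_roi_set(truth, b)
            masks_arm = {}
            for arm in ARMS:
                pk = peaks[arm]
                lines = track(pk.peaks, pk.counts, mask, rois_b.seed_mask, cfg.tracking)
                kept, stats = filter_by_rois(lines, rois_b)
                bm = voxelize(kept, mask.shape)
                masks_arm[arm] = (bm, stats)
            ref_mask, ref_stats = masks_arm["c"]
            bundle_entry = {"visualized": {}, "dsc": {}}
            for arm in ARMS:
                bundle_entry["visualized"][arm] = masks_arm[arm][1]["visualized"]
            if ref_mask.volume == 0:
                bundle_entry["excluded"] = True
            else:
                bundle_entry["excluded"] = False
                for arm in ("a", "b"):
                    bm = masks_arm[arm][0]
                    bundle_entry["dsc"][arm] = (
                        float(dice(bm.data, ref_mask.data)) if bm.volume else None
                    )
                bundle_entry["dsc_truth_c"] = float(
                    dice(ref_mask.data, truth.bundle_masks[b])
                )
            entry[f"bundle{b}"] = bundle_entry
        tracking[method] = entry

    return {
        "params": case.params,
        "n_mask_voxels": int(mask.sum()),
        "ssim_per_axis": [float(s) for s in ssim_axes],
        "ssim_mean": float(np.mean(ssim_axes)),
        "psnr_per_axis": [float(p) for p in psnr_axes],
        "psnr_mean": float(np.mean(psnr_axes)),
        "roi_stats": roi_stats,
        "profile": profile,
        "tracking": tracking,
    }


def _aggregate(cases: list[dict]) -> dict:
    agg: dict = {}
    agg["ssim_mean"] = float(np.mean([c["ssim_mean"] for c in cases]))
    agg["ssim_sd"] = float(np.std([c["ssim_mean"] for c in cases]))
    psnrs = [c["psnr_mean"] for c in cases if np.isfinite(c["psnr_mean"])]
    agg["psnr_mean"] = float(np.mean(psnrs)) if psnrs else None

    for method in METHODS:
        m: dict = {}
        for key in ("jsd_ac", "jsd_bc", "acc_ac", "acc_bc"):
            vals = [c["profile"][method][key] for c in cases]
            m[key] = float(np.mean(vals))
        ja = [c["profile"][method]["jsd_ac"] for c in cases]
        jb = [c["profile"][method]["jsd_bc"] for c in cases]
        aa = [c["profile"][method]["acc_ac"] for c in cases]
        ab = [c["profile"][method]["acc_bc"] for c in cases]
        m["wilcoxon_jsd"] = dataclasses.asdict(paired_compare(ja, jb))
        m["wilcoxon_acc"] = dataclasses.asdict(paired_compare(aa, ab))

        dsc_a, dsc_b, n_excluded = [], [], 0
        visualized = {arm: 0 for arm in ARMS}
        n_bundles = 0
        for c in cases:
            for bundle in c["tracking"][method].values():
                n_bundles += 1
                for arm in ARMS:
                    visualized[arm] += int(bundle["visualized"][arm])
                if bundle.get("excluded") or bundle["dsc"].get("a") is None or (
                    bundle["dsc"].get("b") is None
                ):
                    n_excluded += 1
                    continue
                dsc_a.append(bundle["dsc"]["a"])
                dsc_b.append(bundle["dsc"]["b"])
        m["dsc_ac_mean"] = float(np.mean(dsc_a)) if dsc_a else None
        m["dsc_bc_mean"] = float(np.mean(dsc_b)) if dsc_b else None
        m["n_bundles_compared"] = len(dsc_a)
        m["n_bundles_excluded"] = n_excluded
        m["n_bundles_visualized"] = visualized
        m["n_bundles_total"] = n_bundles
        if dsc_a:
            inc = sum(1 for x, y in zip(dsc_a, dsc_b) if y > x)
            noninf = sum(1 for x, y in zip(dsc_a, dsc_b) if y >= x)
            m["fraction_dsc_increase"] = inc / len(dsc_a)
            m["fraction_dsc_noninferior"] = noninf / len(dsc_a)
            m["wilcoxon_dsc"] = dataclasses.asdict(paired_compare(dsc_a, dsc_b))
        agg[method] = m

    # three-arm Friedman on per-case ROI means (FA and E1)
    stats: dict = {}
    for quantity in ("fa", "e1"):
        per_roi = {}
        roi_names = cases[0]["roi_stats"][quantity]["a"].keys()
        for roi in roi_names:
            arms_vals = {
                arm: [c["roi_stats"][quantity][arm][roi]["mean"] for c in cases]
                for arm in ARMS
            }
            if any(v is None for vals in arms_vals.values() for v in vals):
                continue
            res = paired_compare(
                arms_vals["a"], arms_vals["b"], "friedman_bonferroni", arms_vals["c"]
            )
            per_roi[roi] = dataclasses.asdict(res)
        stats[quantity] = per_roi
    agg["friedman"] = stats
    return agg


def run_experiment(config: ExperimentConfig, outdir=None) -> dict:
    """Run all stages; returns (and optionally writes) the metric report."""
    seeds = _seeds(config.seed)
    scheme = design_scheme(
        config.n_directions,
        seed=seeds["scheme"],
        n_iterations=config.scheme_iterations,
        n_restarts=config.scheme_restarts,
        bvalue=config.bvalue,
    )
    first, second = split_scheme(scheme, config.split_k)
    idx_first, idx_second = _split_indices(scheme, first, second)

    dataset = generate_dataset(scheme, config.phantom, seed=seeds["dataset"])
    train_pairs = _training_pairs(dataset["train"], idx_first, idx_second)
    val_pairs = _training_pairs(dataset["val"], idx_first, idx_second)

    model_cfg = dataclasses.replace(config.model, seed=seeds["model"])
    train_cfg = dataclasses.replace(config.train, seed=seeds["train"])
    model = unet3d.build_model(model_cfg)
    state = unet3d.train(model, train_pairs, val_pairs, train_cfg)

    case_reports = [
        _evaluate_case(case, model, scheme, first, second, idx_first, idx_second, config)
        for case in dataset["test"]
    ]

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "scheme": {
            "n_directions": config.n_directions,
            "energy": scheme.meta["energy"],
            "min_folded_angle_deg": min_folded_angle_deg(scheme.dwi_directions()),
        },
        "training": {
            "train_mse": state.train_mse,
            "val_mse": state.val_mse,
            "best_epoch": state.best_epoch,
            "n_parameters": model.n_parameters,
            "mse_drop_factor": (
                state.train_mse[0] / min(state.train_mse) if state.train_mse else None
            ),
        },
        "cases": case_reports,
        "aggregate": _aggregate(case_reports),
    }
    if outdir is not None:
        _write_report(report, state, Path(outdir))
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=1, default=_json_default)


def _write_report(report: dict, state, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report_to_json(report))
    state.to_csv(outdir / "training_log.csv")
    rows = []
    for i, case in enumerate(report["cases"]):
        for method in METHODS:
            p = case["profile"][method]
            rows.append(
                {
                    "case": i,
                    "method": method,
                    "ssim_mean": case["ssim_mean"],
                    "psnr_mean": case["psnr_mean"],
                    "jsd_ac": p["jsd_ac"],
                    "jsd_bc": p["jsd_bc"],
                    "acc_ac": p["acc_ac"],
                    "acc_bc": p["acc_bc"],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "cases.csv", index=False)
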