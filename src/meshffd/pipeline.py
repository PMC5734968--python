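"""End-to-end coarse-to-fine registration pipeline.

Flow: feature correspondences (SIFT or injected CSV) -> robust global
homography with two-stage outlier rejection -> shape-preserving mesh warp
solved once per constraint weight in the lambda grid -> per-cell weighted
NCC model selection -> coarse backward warp F' -> B-spline FFD refinement
-> fine warp F''.  Metrics (SSD/SAD/NCC/NMI) are evaluated at every stage
on the common valid mask.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import ffd as ffd_mod
from .errors import ValidationError
from .ffd import FFDConfig, FFDResult, fine_warp, optimize
from .global_stage import RobustConfig, detect_and_match, robust_estimate, subimage_refine
from .image import MetricsReport, compute_metrics, save_gray, warp_backward
from .mesh import (LocalHomographySet, MeshEnergyConfig, build_mesh, coarse_warp,
                   select_lambda, solve_mesh)
from .synthetic import CorrespondenceSet
from .wncc import WnccConfig

__all__ = ["PipelineConfig", "RegistrationResult", "register", "report"]


@dataclass
class PipelineConfig:
    """All stage configurations plus pipeline-level switches.

    One beta drives both the mesh cell size and the WNCC support window
    (the method uses a single beta for both).
    """

    beta: int = 16
    robust: RobustConfig = field(default_factory=RobustConfig)
    mesh: MeshEnergyConfig = field(default_factory=MeshEnergyConfig)
    wncc: WnccConfig = field(default_factory=WnccConfig)
    ffd: FFDConfig = field(default_factory=FFDConfig)
    lambda_mode: str = "per-cell"   # or "global"
    skip_coarse: bool = False
    skip_fine: bool = False
    seed: int = 0

    def __post_init__(self):
        self.wncc.beta = self.beta
        self.wncc.delta_s = self.beta / 2.0
        self.robust.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key, sub in (("robust", RobustConfig), ("mesh", MeshEnergyConfig),
                         ("wncc", WnccConfig), ("ffd", FFDConfig)):
            if key in raw:
                kw[key] = sub(**raw.pop(key))
        kw.update(raw)
        return cls(**kw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["mesh"]["lambda_grid"] = [float(v) for v in data["mesh"]["lambda_grid"]]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RegistrationResult:
    """Everything the three registration levels produce."""

    H_g: np.ndarray | None
    correspondences: CorrespondenceSet | None
    refined_inliers: CorrespondenceSet | None
    local_maps: LocalHomographySet | None
    coarse: np.ndarray          # F'
    lattice: object | None      # fitted control lattice
    fine: np.ndarray            # F''
    ffd_result: FFDResult | None
    metrics: dict               # stage -> MetricsReport
    mask: np.ndarray            # common valid mask
    logs: list


def register(ref: np.ndarray, flt: np.ndarray,
             cfg: PipelineConfig | None = None,
             correspondences: CorrespondenceSet | None = None) -> RegistrationResult:
    """Run the full coarse-to-fine registration of ``flt`` onto ``ref``."""
    cfg = cfg or PipelineConfig()
    ref = np.asarray(ref, dtype=float)
    flt = np.asarray(flt, dtype=float)
    if ref.ndim != 2 or flt.ndim != 2:
        raise ValidationError("images must be 2-D grayscale arrays")
    h, w = ref.shape
    logs = []

    def log(stage, **kv):
        logs.append({"stage": stage, "time": time.time(), **kv})

    H_g = None
    pairs = None
    refined = None
    local_maps = None
    coarse_img = flt
    valid_c = np.ones_like(ref, dtype=bool)

    if not cfg.skip_coarse:
        t0 = time.time()
        if correspondences is None:
            pairs = detect_and_match(ref, flt, ratio=cfg.robust.ratio)
        else:
            pairs = correspondences
        H_g, labeled = robust_estimate(pairs, cfg.robust)
        inliers = labeled.subset(labeled.inlier)
        refined = subimage_refine((w, h), inliers, cfg.robust)
        pairs = labeled
        log("global", n_matches=len(labeled), n_inliers=int(labeled.inlier.sum()),
            n_refined=len(refined), seconds=round(time.time() - t0, 3))

        t0 = time.time()
        mesh = build_mesh(w, h, cfg.beta)
        solutions = [(lam, solve_mesh(refined, H_g, mesh, lam, cfg.mesh))
                     for lam in cfg.mesh.lambda_grid]
        local_maps = select_lambda(solutions, ref, flt, H_g, mesh, cfg.wncc,
                                   mode=cfg.lambda_mode)
        coarse_img, valid_c = coarse_warp(flt, local_maps, (w, h))
        lam_vals, lam_counts = np.unique(local_maps.chosen_lambda,
                                         return_counts=True)
        log("coarse", lambda_histogram={float(v): int(c) for v, c
                                        in zip(lam_vals, lam_counts)},
            seconds=round(time.time() - t0, 3))

    lattice = None
    ffd_result = None
    fine_img = coarse_img
    valid_f = valid_c.copy()
    if not cfg.skip_fine:
        t0 = time.time()
        ffd_result = optimize(ref, coarse_img, cfg.ffd)
        lattice = ffd_result.lattice
        fine_img, vf = fine_warp(coarse_img, lattice)
        # propagate the coarse validity through the fine transform
        vc_f, _ = warp_backward(valid_c.astype(float),
                                lambda p: ffd_mod.ffd_transform(lattice, p),
                                out_shape=ref.shape)
        valid_f = vf & (vc_f > 0.999)
        log("fine", n_iters=ffd_result.n_iters,
            final_grad_norm=(ffd_result.grad_norms[-1]
                             if ffd_result.grad_norms else None),
            final_cost=ffd_result.cost_trace[-1],
            seconds=round(time.time() - t0, 3))

    mask = valid_c & valid_f
    metrics = {
        "initial": compute_metrics(ref, flt, cfg.ffd.bins, mask=mask),
        "coarse": compute_metrics(ref, coarse_img, cfg.ffd.bins, mask=mask),
        "fine": compute_metrics(ref, fine_img, cfg.ffd.bins, mask=mask),
    }
    return RegistrationResult(H_g=H_g, correspondences=pairs,
                              refined_inliers=refined, local_maps=local_maps,
                              coarse=coarse_img, lattice=lattice,
                              fine=fine_img, ffd_result=ffd_result,
                              metrics=metrics, mask=mask, logs=logs)


def report(result: RegistrationResult, out_dir, ref: np.ndarray | None = None,
           cfg: PipelineConfig | None = None) -> list:
    """Write metrics CSV, difference images, mesh/lattice dumps and a log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "metrics.csv"
    with open(path, "w") as fh:
        fh.write("stage,ssd,sad,ncc,nmi\n")
        for stage, m in result.metrics.items():
            fh.write(f"{stage},{m.ssd!r},{m.sad!r},{m.ncc!r},{m.nmi!r}\n")
    written.append(path)

    if ref is not None:
        for stage, img in (("coarse", result.coarse), ("fine", result.fine)):
            p = out / f"diff_{stage}.png"
            save_gray(p, np.clip(np.abs(ref - img), 0, 1))
            written.append(p)

    if result.local_maps is not None:
        p = out / "mesh_lambda.csv"
        lm = result.local_maps
        with open(p, "w") as fh:
            fh.write("cell_j,cell_k,chosen_lambda,wncc\n")
            for j in range(lm.mesh.n_cols):
                for k in range(lm.mesh.n_rows):
                    fh.write(f"{j},{k},{lm.chosen_lambda[j, k]!r},"
                             f"{lm.score[j, k]!r}\n")
        written.append(p)

    if result.lattice is not None:
        p = out / "lattice.csv"
        result.lattice.to_csv(p)
        written.append(p)

    if result.correspondences is not None:
        p = out / "correspondences.csv"
        result.correspondences.to_csv(p)
        written.append(p)

    p = out / "run_log.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump({"log": result.logs}, fh, sort_keys=False)
    written.append(p)
    if cfg is not None:
        p = out / "config_echo.yaml"
        cfg.to_yaml(p)
        written.append(p)
    return written
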