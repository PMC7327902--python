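"""End-to-end workflows combining synthesis, image analysis, and fitting.

These helpers drive the whole chain — generate a titration of synthetic
scenes at known ground-truth Hill parameters, analyze every image, assemble
the measured binding isotherm, and fit it — and are shared by the CLI and
the validation suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import imaging, synth
from .isotherm import (BindingIsotherm, HillParameters, compute_free_ligand,
                       fit_hill, hill_response)
from .latticesim import TITRATION_NM

__all__ = [
    "self_consistent_coverage",
    "ImageTitrationResult",
    "run_image_titration",
]


def self_consistent_coverage(total_nm: float, kd: float, n_h: float) -> float:
    """Equilibrium coverage under the 1:1 ligand:site stoichiometric design.

    Solves θ = H(c·(1−θ)) where H is the Hill isotherm and c·(1−θ) the free
    ligand left after θ·c is bound (site concentration equals the ligand total
    under 1:1:7 reconstitution).
    """
    if total_nm <= 0:
        return 0.0
    f = lambda th: th - hill_response(total_nm * (1.0 - th), kd, n_h)
    return float(brentq(f, 0.0, 1.0 - 1e-9))


@dataclass
class ImageTitrationResult:
    """Measured isotherm and fit from a synthetic image titration."""

    isotherm: BindingIsotherm
    fit: HillParameters
    true_kd: float
    true_n_h: float
    theta_true: np.ndarray
    per_image_theta: list[list[float]]


def run_image_titration(
    kd: float,
    n_h: float,
    seed: int,
    totals_nm: Sequence[float] = TITRATION_NM,
    n_images: int = 5,
    n_filaments: int = 25,
    image_shape: tuple[int, int] = (384, 384),
    binarize_params: imaging.BinarizeParams | None = None,
    outdir: str | Path | None = None,
    group: str = "",
) -> ImageTitrationResult:
    """Generate, analyze and fit one full synthetic image titration.

    For each total concentration the ground-truth coverage follows the Hill
    law self-consistently with free-ligand depletion; ``n_images`` replicate
    scenes are rendered and analyzed, the measured θ corrects the free
    concentration (free = total − θ·site_conc with site_conc = total), and the
    Hill equation is fitted to the mean ± SD isotherm with the plateau fixed
    at 1.  Scenes are optionally written to ``outdir`` as TIFF bundles.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    mean_th, sd_th, frees, theta_true, per_image = [], [], [], [], []
    for i, total in enumerate(totals_nm):
        th_true = self_consistent_coverage(total, kd, n_h)
        free_true = total * (1.0 - th_true)
        theta_true.append(th_true)
        ths = []
        for j in range(n_images):
            s = (seed * 1009 + i * 13 + j) % (2**31)
            spec = synth.SceneSpec(n_filaments=n_filaments, seed=s,
                                   hill_params=(kd, n_h, free_true))
            render = synth.RenderConfig(image_shape=image_shape, seed=s + 7)
            img, gts = synth.make_scene(spec, render)
            if outdir is not None:
                img.meta = dict(img.meta or {}, ligand_total_nm=total, group=group)
                synth.write_scene(img, outdir / f"scene_c{i}_r{j}", ground_truths=gts)
            _, summary = imaging.analyze_image(img, binarize_params, group=group)
            ths.append(summary["theta"])
        per_image.append(ths)
        th_hat = float(np.mean(ths))
        mean_th.append(th_hat)
        sd_th.append(max(float(np.std(ths, ddof=1)), 1e-3) if len(ths) > 1 else 1e-3)
        frees.append(compute_free_ligand(total, th_hat, total))
    order = np.argsort(frees)
    iso = BindingIsotherm(
        concentrations=np.asarray(frees)[order],
        response=np.asarray(mean_th)[order],
        sd=np.asarray(sd_th)[order],
        n=np.full(len(totals_nm), n_images)[order],
        response_kind="saturation",
        group=group,
    )
    fit = fit_hill(iso, fix_scale=1.0)
    return ImageTitrationResult(
        isotherm=iso,
        fit=fit,
        true_kd=kd,
        true_n_h=n_h,
        theta_true=np.asarray(theta_true),
        per_image_theta=per_image,
    )
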