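"""Image-quality metrics: SSIM, L1/L2 error norms, per-ROI CNR, phase smoothness."""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from skimage.metrics import structural_similarity

from .phantom import TISSUE_LABELS

__all__ = ["ssim", "error_norms", "cnr", "phase_smoothness", "QualityReport"]


def ssim(x: np.ndarray, y: np.ndarray, data_range: float | None = None) -> float:
    """Structural similarity between two magnitude images.

    Standard Wang et al. settings: Gaussian window sigma = 1.5,
    K1 = 0.01, K2 = 0.03; ``data_range`` defaults to the maximum of the
    reference ``y``.  Accepts any same-shape crop, so region-of-interest
    (zoomed) SSIM is computed by slicing before the call.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    if data_range is None:
        data_range = float(max(y.max(), np.finfo(float).tiny))
    return float(
        structural_similarity(
            x,
            y,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def error_norms(
    x: np.ndarray, y: np.ndarray, normalize: bool = False
) -> tuple[float, float]:
    """L1 and L2 norms of the magnitude difference ``|x| - |y|``.

    With ``normalize=True`` each norm is divided by the corresponding norm
    of ``|y|`` (so the L2 value is the NRMSE against ``y``).
    """
    x = np.abs(np.asarray(x))
    y = np.abs(np.asarray(y))
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    diff = x - y
    l1 = float(np.abs(diff).sum())
    l2 = float(np.linalg.norm(diff))
    if normalize:
        l1 /= float(np.abs(y).sum())
        l2 /= float(np.linalg.norm(y))
    return l1, l2


def cnr(
    img: np.ndarray,
    labels: np.ndarray,
    roi: str | int,
    reference_roi: str | int = "background",
    noise_roi: str | int = "background",
) -> float:
    """Contrast-to-noise ratio of a labelled region.

    ``CNR = |mean(roi) - mean(reference)| / std(noise_roi)`` on the
    magnitude image.  By default both the contrast reference and the noise
    region are the background (air), making the value a per-tissue
    signal-to-background-noise contrast; the regions used are part of the
    metric's definition and should be reported with it.
    """
    img = np.abs(np.asarray(img))

    def mask_of(name):
        code = TISSUE_LABELS[name] if isinstance(name, str) else int(name)
        m = labels == code
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty")
        return m

    m_roi = mask_of(roi)
    m_ref = mask_of(reference_roi)
    m_noise = mask_of(noise_roi)
    noise_std = float(img[m_noise].std())
    if noise_std == 0:
        raise ValueError("noise ROI has zero standard deviation")
    return float(abs(img[m_roi].mean() - img[m_ref].mean()) / noise_std)


def phase_smoothness(img: np.ndarray, support: np.ndarray | None = None) -> float:
    """Mean absolute wrapped phase difference between 4-neighbours.

    Lower is smoother; a pure linear phase ramp of slope ``s`` rad/pixel
    scores ``|s|``.  Only neighbour pairs with both pixels inside
    ``support`` contribute.
    """
    img = np.asarray(img)
    if support is None:
        support = np.ones(img.shape, dtype=bool)
    support = np.asarray(support, dtype=bool)
    if not support.any():
        raise ValueError("support is empty")
    diffs = []
    for ax in (0, 1):
        a = img.take(range(1, img.shape[ax]), axis=ax)
        b = img.take(range(0, img.shape[ax] - 1), axis=ax)
        pair = support.take(range(1, img.shape[ax]), axis=ax) & support.take(
            range(0, img.shape[ax] - 1), axis=ax
        )
        d = np.angle(a * np.conj(b))  # wrapped difference in (-pi, pi]
        diffs.append(np.abs(d[pair]))
    all_d = np.concatenate(diffs)
    if all_d.size == 0:
        return 0.0
    return float(all_d.mean())


@dataclass
class QualityReport:
    """Bundle of image-quality metrics for one reconstruction."""

    ssim: float
    l1_error: float
    l2_error: float
    cnr_table: dict = field(default_factory=dict)
    phase_smoothness: float | None = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def evaluate(
        cls,
        recon: np.ndarray,
        truth: np.ndarray,
        labels: np.ndarray | None = None,
        tissues: tuple = ("gm", "wm", "csf", "thalamus", "gp", "cn", "putamen"),
        support: np.ndarray | None = None,
        normalize_norms: bool = True,
        cnr_noise_roi: str | int = "wm",
    ) -> "QualityReport":
        """Compute all metrics against a ground truth.

        The CNR noise region defaults to white matter rather than
        background air: on synthetic data the air is exactly zero, so a
        denoising reconstruction drives its standard deviation towards
        zero and the air-referenced ratio degenerates.
        """
        mag_r = np.abs(recon)
        mag_t = np.abs(truth)
        l1, l2 = error_norms(mag_r, mag_t, normalize=normalize_norms)
        table = {}
        if labels is not None:
            table = {
                t: cnr(mag_r, labels, t, noise_roi=cnr_noise_roi) for t in tissues
            }
        return cls(
            ssim=ssim(mag_r, mag_t),
            l1_error=l1,
            l2_error=l2,
            cnr_table=table,
            phase_smoothness=phase_smoothness(recon, support),
            metadata={
                "cnr_reference_roi": "background",
                "cnr_noise_roi": cnr_noise_roi,
                "norms_normalized": normalize_norms,
            },
        )

    def to_json(self) -> str:
        d = {
            "ssim": self.ssim,
            "l1_error": self.l1_error,
            "l2_error": self.l2_error,
            "cnr": self.cnr_table,
            "phase_smoothness": self.phase_smoothness,
            "metadata": self.metadata,
        }
        return json.dumps(d, indent=2)

    def to_markdown(self) -> str:
        lines = [
            "| metric | value |",
            "|---|---|",
            f"| SSIM | {self.ssim:.4f} |",
            f"| L1 error | {self.l1_error:.4g} |",
            f"| L2 error | {self.l2_error:.4g} |",
        ]
        if self.phase_smoothness is not None:
            lines.append(f"| phase smoothness | {self.phase_smoothness:.4g} |")
        for tissue, value in self.cnr_table.items():
            lines.append(f"| CNR {tissue} | {value:.1f} |")
        return "\n".join(lines)
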