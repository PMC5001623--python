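"""Model/Results front-end over the segmentation engine.

``MLGOCModel`` bundles an image with the shape prior, the intensity
model and the run configuration; ``fit`` runs the energy minimisation
and returns an ``MLGOCResults`` carrying the converged field, the
extracted instances, convergence diagnostics and a printable summary —
the same division of labour as the model/results pairs in the classical
statistical modelling packages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import (
    SegmentationConfig,
    segment_image,
)
from .extraction import InstanceSet
from .goc import GOCParams, build_interaction_kernel, calibrate_for_radius
from .intensity import ImageFormationParams, estimate_params_mle

__all__ = ["MLGOCModel", "MLGOCResults"]


class MLGOCModel:
    """Multi-layer gas-of-near-circles segmentation model for one image.

    Parameters
    ----------
    image : 2-D array
        Single-channel intensity image in native units.
    goc : GOCParams, optional
        Shape-prior weights.  When omitted, calibrated from ``r_hat``.
    imaging : ImageFormationParams, optional
        Additive intensity model.  When omitted, estimated from the
        image by Gaussian MLE over an Otsu fore/background split.
    config : SegmentationConfig, optional
        Engine configuration (layers, data weight, descent controls).
    r_hat : float, optional
        Preferred nucleus radius in pixels; used when ``goc`` is omitted.
    """

    def __init__(self, image, goc=None, imaging=None, config=None, r_hat=None):
        self.image = np.asarray(image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("image must be a single-channel 2-D array")
        if goc is None:
            if r_hat is None:
                raise ValueError("provide goc parameters or r_hat to calibrate them")
            goc = calibrate_for_radius(float(r_hat))
        self.goc: GOCParams = goc
        self.imaging: ImageFormationParams = (
            imaging if imaging is not None else estimate_params_mle(self.image)
        )
        self.config: SegmentationConfig = config or SegmentationConfig()
        self.kernel = build_interaction_kernel(goc.d, goc.epsilon)

    @classmethod
    def from_file(cls, path, **kwargs) -> "MLGOCModel":
        from .io import read_image

        return cls(read_image(path), **kwargs)

    def fit(self, seeds=None) -> "MLGOCResults":
        """Minimise the total energy and extract object instances."""
        field, instances, diag = segment_image(
            self.image, self.goc, self.imaging, self.config,
            seeds=seeds, kernel=self.kernel,
        )
        return MLGOCResults(self, field, instances, diag)


class MLGOCResults:
    """Converged segmentation with diagnostics."""

    def __init__(self, model: MLGOCModel, field, instances: InstanceSet, diagnostics):
        self.model = model
        self.field = field
        self.instances = instances
        self.diagnostics = diagnostics

    @property
    def n_objects(self) -> int:
        return len(self.instances)

    @property
    def converged(self) -> bool:
        return self.diagnostics.converged

    @property
    def final_energy(self) -> float:
        return self.diagnostics.energy_trace[-1]

    @property
    def energy_trace(self) -> np.ndarray:
        return np.asarray(self.diagnostics.energy_trace)

    def objects_frame(self) -> pd.DataFrame:
        """Per-object table: layer, area, centroid, equivalent radius."""
        rows = []
        for mask, layer in zip(self.instances.masks, self.instances.layer_of):
            ys, xs = np.nonzero(mask)
            area = len(ys)
            rows.append(
                {
                    "layer": layer,
                    "area_px": area,
                    "centroid_x": float(xs.mean()),
                    "centroid_y": float(ys.mean()),
                    "equiv_radius": float(np.sqrt(area / np.pi)),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m, d = self.model, self.diagnostics
        lines = [
            "          MLGOC segmentation results",
            "=" * 48,
            f"image size:        {m.image.shape[0]} x {m.image.shape[1]} px",
            f"layers:            {self.field.n_layers}",
            f"preferred radius:  {m.goc.r_hat:.1f} px   (d={m.goc.d:.1f}, eps={m.goc.epsilon:.1f})",
            f"prior weights:     D={m.goc.D:.3g} lambda={m.goc.lambda_f:.3g} "
            f"alpha={m.goc.alpha_f:.3g} beta={m.goc.beta_f:.3g}",
            f"intensity model:   mu-={m.imaging.mu_minus:.2f} s2-={m.imaging.sigma2_minus:.2f} "
            f"dmu={m.imaging.delta_mu:.2f} ds2={m.imaging.delta_sigma2:.2f}",
            f"data weight:       gamma_d={m.config.gamma_d:.3g}",
            f"iterations:        {d.iterations} ({'converged' if d.converged else 'max_iter'})",
            f"final energy:      {self.final_energy:.4f}",
            f"objects found:     {self.n_objects}",
        ]
        frame = self.objects_frame()
        if len(frame):
            lines.append("-" * 48)
            lines.append(frame.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
        return "\n".join(lines)

    def plot_overlay(self, ax=None):
        """Image with instance contours coloured by layer."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.model.image, cmap="gray")
        cmap = plt.get_cmap("tab10")
        for mask, layer in zip(self.instances.masks, self.instances.layer_of):
            ax.contour(mask.astype(float), levels=[0.5], colors=[cmap(layer % 10)])
        ax.set_axis_off()
        return ax

    def save_label_stack(self, path) -> None:
        from .io import write_label_stack

        write_label_stack(self.instances, path)
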