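"""High-level modelling interface.

:class:`PtychographyModel` wraps a diffraction dataset the way a
statistical model wraps its data: construct it from a
:class:`~ptychokit.data_model.DiffractionStack` (or a dataset file),
call :meth:`fit` with an engine chain, and receive a
:class:`PtychographyResults` carrying the estimates (object and probe),
the misfit trace, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .data_model import (
    DiffractionStack,
    ObjectField,
    ProbeStack,
    ReconConfig,
    ReconResult,
    effective_pixel_size,
)
from .projection import run_reconstruction


def _parse_chain(engine, iterations, **kwargs) -> list:
    """Accept 'dm', 'rpie:100,ap:300', or ready-made ReconConfig lists."""
    if isinstance(engine, ReconConfig):
        return [engine]
    if isinstance(engine, (list, tuple)):
        return [
            e if isinstance(e, ReconConfig) else ReconConfig(
                engine=e[0], iterations=e[1], **kwargs
            )
            for e in engine
        ]
    blocks = []
    for part in str(engine).split(","):
        if ":" in part:
            name, its = part.split(":")
            blocks.append(ReconConfig(engine=name.strip(), iterations=int(its),
                                      **kwargs))
        else:
            blocks.append(ReconConfig(engine=part.strip(), iterations=iterations,
                                      **kwargs))
    return blocks


class PtychographyModel:
    """Joint object/probe model of a ptychographic acquisition."""

    def __init__(self, stack: DiffractionStack):
        self.stack = stack

    @classmethod
    def from_file(cls, path: str) -> "PtychographyModel":
        from .io import load_dataset

        return cls(load_dataset(path))

    def fit(
        self,
        engine: Union[str, ReconConfig, Sequence] = "dm",
        iterations: int = 100,
        *,
        init: Optional[dict] = None,
        **engine_kwargs,
    ) -> "PtychographyResults":
        """Run the reconstruction and return a results object.

        ``engine`` may be a single engine name, a chain specification
        like ``"rpie:100,ap:300"``, or (a list of)
        :class:`ReconConfig`; extra keyword arguments are forwarded to
        every generated config.
        """
        chain = _parse_chain(engine, iterations, **engine_kwargs)
        raw = run_reconstruction(self.stack, chain, init=init)
        return PtychographyResults(self, raw)


class PtychographyResults:
    """Estimates and diagnostics of a fitted ptychography model."""

    def __init__(self, model: PtychographyModel, raw: ReconResult):
        self.model = model
        self._raw = raw

    @property
    def object(self) -> ObjectField:
        return self._raw.object

    @property
    def probe(self) -> ProbeStack:
        return self._raw.probe

    @property
    def error_trace(self) -> np.ndarray:
        return self._raw.error_trace

    @property
    def final_error(self) -> float:
        return float(self._raw.error_trace[-1]) if len(self._raw.error_trace) else np.nan

    @property
    def raw(self) -> ReconResult:
        return self._raw

    def nmse(self, truth_object, truth_probe=None, mask=None) -> float:
        """Ambiguity-corrected NMSE against a known ground truth.

        By default only the scan-covered region of the canvas is scored;
        pixels the data never constrained are excluded.
        """
        from .postprocess import coverage_mask, register_to_ground_truth

        if (
            mask is None
            and self._raw.offsets_px is not None
            and self.object.shape == truth_object.values.shape
        ):
            mask = coverage_mask(
                self.probe, self._raw.offsets_px, truth_object.values.shape
            )
        value, _ = register_to_ground_truth(
            self._raw, truth_object, truth_probe, mask
        )
        return value

    def summary(self) -> str:
        g = self.model.stack.geometry
        chain = ", ".join(
            f"{c.engine}:{c.iterations}" for c in self._raw.config_echo
        ) or "(none)"
        px = effective_pixel_size(g) if g.regime == "far_field" else g.pixel_m
        rows = [
            ("Frames", f"{self.model.stack.n_frames}"),
            ("Frame shape", f"{g.frame_shape[0]} x {g.frame_shape[1]}"),
            ("Energy", f"{g.energy_keV:g} keV"),
            ("Distance", f"{g.distance_m:g} m"),
            ("Effective pixel", f"{px * 1e9:.2f} nm"),
            ("Object canvas", f"{self.object.shape[0]} x {self.object.shape[1]}"),
            ("Probe modes", f"{self.probe.n_modes}"),
            ("Engine chain", chain),
            ("Iterations run", f"{len(self.error_trace)}"),
            ("Final misfit", f"{self.final_error:.3e}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Ptychography Reconstruction Results",
                 "=" * 38]
        lines += [f"{k.ljust(width)} : {v}" for k, v in rows]
        return "\n".join(lines)

    def plot(self, filename: Optional[str] = None):
        """Magnitude/phase of the object, leading probe mode, misfit trace."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(9, 8))
        axes[0, 0].imshow(np.abs(self.object.values), cmap="gray")
        axes[0, 0].set_title("object magnitude")
        axes[0, 1].imshow(np.angle(self.object.values), cmap="twilight")
        axes[0, 1].set_title("object phase")
        axes[1, 0].imshow(np.abs(self.probe.modes[0]), cmap="viridis")
        axes[1, 0].set_title("probe mode 0 magnitude")
        axes[1, 1].semilogy(self.error_trace)
        axes[1, 1].set_title("misfit trace")
        axes[1, 1].set_xlabel("iteration")
        fig.tight_layout()
        if filename:
            fig.savefig(filename, dpi=120)
            plt.close(fig)
        return fig

    def save(self, path: str) -> None:
        from .io import save_dataset

        save_dataset(
            self.model.stack,
            path,
            initial_object=self.object,
            initial_probe=self.probe,
        )
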