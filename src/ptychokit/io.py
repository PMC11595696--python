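"""Readers and writers for the on-disk dataset container.

The native container is an HDF5 file with a CXI-style tree::

    entry_1/
      data_1/data                     N x M x M float32 intensities
      data_1/mask                     binary trust mask (optional)
      sample_1/geometry_1/translation N x 3 metric positions (x, y, z)
      instrument_1/source_1/energy_keV
      instrument_1/detector_1/{distance, x_pixel_size, regime}
      initial_1/{object, probe}       optional complex64 initial guesses
      ground_truth/{object, probe}    optional simulator ground truth

A ``ptychokit_layout`` attribute on the root guards dialect drift.  A
plain directory of TIFF frames plus a CSV of positions (columns
``index,x_m,y_m``) is accepted for interoperability.
"""

from __future__ import annotations

import csv
import os
from typing import Optional, Tuple

import h5py
import numpy as np

from .data_model import (
    DatasetLayoutError,
    DetectorGeometry,
    DiffractionStack,
    ObjectField,
    ProbeStack,
    ScanPattern,
)

LAYOUT_VERSION = 1


def save_dataset(
    stack: DiffractionStack,
    path: str,
    *,
    initial_object: Optional[ObjectField] = None,
    initial_probe: Optional[ProbeStack] = None,
    ground_truth_object: Optional[ObjectField] = None,
    ground_truth_probe: Optional[ProbeStack] = None,
    compression: Optional[str] = None,
) -> None:
    """Write a :class:`DiffractionStack` (plus optional guesses/truth)."""
    with h5py.File(path, "w") as f:
        f.attrs["ptychokit_layout"] = LAYOUT_VERSION
        data = f.create_group("entry_1/data_1")
        data.create_dataset(
            "data", data=stack.intensities.astype(np.float32), compression=compression
        )
        data.create_dataset("mask", data=stack.masks.astype(np.uint8))
        # CXI stores (x, y, z) triples; internal order is (y, x).
        pos = stack.scan.positions_m
        translation = np.zeros((len(pos), 3))
        translation[:, 0] = pos[:, 1]
        translation[:, 1] = pos[:, 0]
        f.create_dataset("entry_1/sample_1/geometry_1/translation", data=translation)
        g = stack.geometry
        inst = f.create_group("entry_1/instrument_1")
        inst.create_dataset("source_1/energy_keV", data=g.energy_keV)
        det = inst.create_group("detector_1")
        det.create_dataset("distance", data=g.distance_m)
        det.create_dataset("x_pixel_size", data=g.pixel_m)
        det.create_dataset("y_pixel_size", data=g.pixel_m)
        det.attrs["regime"] = g.regime
        for name, obj, probe in (
            ("entry_1/initial_1", initial_object, initial_probe),
            ("ground_truth", ground_truth_object, ground_truth_probe),
        ):
            if obj is not None:
                f.create_dataset(
                    f"{name}/object", data=obj.values.astype(np.complex64)
                )
                f[name].attrs["object_pixel_m"] = obj.pixel_m
            if probe is not None:
                f.create_dataset(
                    f"{name}/probe", data=probe.modes.astype(np.complex64)
                )
                f[name].create_dataset("occupancies", data=probe.occupancies)


def _read_complex_group(
    f: h5py.File, name: str, pixel_m: float
) -> Tuple[Optional[ObjectField], Optional[ProbeStack]]:
    obj = probe = None
    if name in f:
        grp = f[name]
        if "object" in grp:
            px = float(grp.attrs.get("object_pixel_m", pixel_m))
            obj = ObjectField(np.asarray(grp["object"], dtype=complex), px)
        if "probe" in grp:
            occ = np.asarray(grp["occupancies"]) if "occupancies" in grp else None
            probe = ProbeStack(np.asarray(grp["probe"], dtype=complex), occ)
    return obj, probe


def load_dataset(path: str, *, with_extras: bool = False):
    """Load a dataset container written by :func:`save_dataset`.

    Returns the :class:`DiffractionStack`; with ``with_extras=True`` a
    tuple ``(stack, extras)`` where ``extras`` maps the optional groups
    (``initial_object``, ``initial_probe``, ``ground_truth_object``,
    ``ground_truth_probe``) to their contents or ``None``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("ptychokit_layout")
        if version is None:
            raise DatasetLayoutError(f"{path}: missing ptychokit_layout attribute")
        if int(version) != LAYOUT_VERSION:
            raise DatasetLayoutError(
                f"{path}: unknown layout version {version} (expected {LAYOUT_VERSION})"
            )
        try:
            intensities = np.asarray(f["entry_1/data_1/data"], dtype=float)
            translation = np.asarray(f["entry_1/sample_1/geometry_1/translation"])
            energy = float(f["entry_1/instrument_1/source_1/energy_keV"][()])
            det = f["entry_1/instrument_1/detector_1"]
            distance = float(det["distance"][()])
            pixel = float(det["x_pixel_size"][()])
            regime = det.attrs.get("regime", "far_field")
        except KeyError as exc:
            raise DatasetLayoutError(f"{path}: missing dataset {exc}") from exc
        if intensities.ndim != 3:
            raise DatasetLayoutError(
                f"{path}: entry_1/data_1/data must be 3-D, got shape "
                f"{intensities.shape}"
            )
        n = intensities.shape[0]
        if translation.shape[0] != n:
            raise DatasetLayoutError(
                f"{path}: entry_1/data_1/data holds {n} frames but translation "
                f"holds {translation.shape[0]} positions"
            )
        positions = np.column_stack([translation[:, 1], translation[:, 0]])
        masks = (
            np.asarray(f["entry_1/data_1/mask"])
            if "entry_1/data_1/mask" in f
            else None
        )
        geometry = DetectorGeometry(
            energy_keV=energy,
            distance_m=distance,
            pixel_m=pixel,
            frame_shape=intensities.shape[1:],
            regime=str(regime),
        )
        stack = DiffractionStack(
            intensities=intensities,
            scan=ScanPattern(positions),
            geometry=geometry,
            masks=masks,
        )
        if not with_extras:
            return stack
        from .data_model import effective_pixel_size

        px = effective_pixel_size(geometry) if regime == "far_field" else pixel
        init_obj, init_probe = _read_complex_group(f, "entry_1/initial_1", px)
        gt_obj, gt_probe = _read_complex_group(f, "ground_truth", px)
        extras = {
            "initial_object": init_obj,
            "initial_probe": init_probe,
            "ground_truth_object": gt_obj,
            "ground_truth_probe": gt_probe,
        }
        return stack, extras


def load_tiff_directory(
    directory: str, geometry: DetectorGeometry
) -> DiffractionStack:
    """Read a directory of TIFF frames plus ``positions.csv``.

    The CSV must have columns ``index,x_m,y_m``; frame files are matched
    by sorted name order against the sorted indices.
    """
    import tifffile

    csv_path = os.path.join(directory, "positions.csv")
    if not os.path.exists(csv_path):
        raise DatasetLayoutError(f"{directory}: positions.csv not found")
    rows = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append((int(row["index"]), float(row["x_m"]), float(row["y_m"])))
    rows.sort()
    tiffs = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.lower().endswith((".tif", ".tiff"))
    )
    if len(tiffs) != len(rows):
        raise DatasetLayoutError(
            f"{directory}: {len(tiffs)} TIFF frames but {len(rows)} CSV rows"
        )
    frames = np.stack([tifffile.imread(t) for t in tiffs]).astype(float)
    positions = np.array([[y, x] for _, x, y in rows])
    return DiffractionStack(
        intensities=frames,
        scan=ScanPattern(positions),
        geometry=geometry,
    )
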