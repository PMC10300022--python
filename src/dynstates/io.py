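"""Plain-text readers and writers for pipeline artefacts.

Series are TSV (T rows x M columns, no header) with a JSON sidecar; matrices
are TSV with optional label headers; lesion masks are NIfTI; the ground
truth and fitted model are JSON (covariances as per-state TSV).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .preprocess import ICTimeSeries
from .simulate import GroundTruth, LesionMask, SimulatedSubject

__all__ = [
    "write_subject",
    "read_subject",
    "write_ground_truth",
    "read_ground_truth",
    "write_matrix",
    "read_matrix",
    "write_lesion_nifti",
    "read_motion_params",
    "sha256_of",
]


def write_subject(directory, sub: SimulatedSubject | ICTimeSeries, seed=None) -> list:
    """TSV series + JSON sidecar (+ true path for simulated subjects)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / sub.subject_id
    np.savetxt(f"{base}.tsv", sub.series, delimiter="\t", fmt="%.8g")
    sidecar = {"subject_id": sub.subject_id, "group": sub.group, "TR": sub.TR}
    if seed is not None:
        sidecar["seed"] = int(seed)
    files = [f"{base}.tsv", f"{base}.json"]
    if isinstance(sub, SimulatedSubject):
        np.savetxt(f"{base}_truepath.tsv", sub.true_path, fmt="%d")
        files.append(f"{base}_truepath.tsv")
    with open(f"{base}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return files


def read_subject(tsv_path) -> ICTimeSeries:
    tsv_path = Path(tsv_path)
    series = np.loadtxt(tsv_path, delimiter="\t", ndmin=2)
    with open(tsv_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return ICTimeSeries(series=series, TR=float(meta["TR"]),
                        subject_id=meta["subject_id"], group=meta.get("group", ""))


def write_ground_truth(path, gt: GroundTruth) -> None:
    payload = {
        "K": gt.K, "M": gt.M, "seed": gt.seed,
        "block_assign": gt.block_assign.tolist(),
        "pi": {g: v.tolist() for g, v in gt.pi.items()},
        "A": {g: v.tolist() for g, v in gt.A.items()},
        "mu": gt.mu.tolist(),
        "Sigma": gt.Sigma.tolist(),
        "attenuation": gt.attenuation.tolist(),
        "healthy_states": list(gt.healthy_states),
        "pathological_states": list(gt.pathological_states),
        "hemisphere_convention": "first-axis midpoint split",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        K=d["K"], M=d["M"],
        block_assign=np.asarray(d["block_assign"]),
        pi={g: np.asarray(v) for g, v in d["pi"].items()},
        A={g: np.asarray(v) for g, v in d["A"].items()},
        mu=np.asarray(d["mu"]), Sigma=np.asarray(d["Sigma"]),
        attenuation=np.asarray(d["attenuation"]),
        healthy_states=d["healthy_states"],
        pathological_states=d["pathological_states"],
        seed=d["seed"],
    )


def write_matrix(path, matrix: np.ndarray, labels=None) -> None:
    """TSV matrix; optional label header row (tab-separated, '#'-prefixed)."""
    header = "\t".join(str(x) for x in labels) if labels is not None else ""
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.8g", header=header)


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_lesion_nifti(path, lesion: LesionMask) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(lesion.mask.astype(np.uint8), affine=np.eye(4))
    img.header["descrip"] = b"synthetic lesion; hemisphere by first-axis midpoint"
    nib.save(img, str(path))


def read_motion_params(path) -> np.ndarray:
    """Whitespace-delimited T x 6 motion parameter file."""
    mp = np.loadtxt(path, ndmin=2)
    if mp.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {mp.shape[1]}")
    return mp


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
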