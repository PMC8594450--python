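"""Dataset persistence, manifests, and fixture generation.

Image ensembles persist to HDF5 (`images` [N,H,W] float32, `labels` [N]
int8, attributes holding the generating spec and seeds as JSON). Single
images export to 8-bit PNG with the min-max scale recorded in the PNG text
metadata. A :class:`DatasetManifest` records content hashes so any mutation
of stored ensembles is detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
from PIL import Image
from PIL.PngImagePlugin import PngInfo

import iqtask
from iqtask._rng import stream_rng
from iqtask.imaging import ImagingEnsemble, NoiseSpec, build_task_ensembles
from iqtask.phantoms import CLBParams, MCClusterSpec, ObjectImage

__all__ = [
    "save_ensemble",
    "load_ensemble",
    "export_png",
    "DatasetManifest",
    "make_fixtures",
]


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__type__": type(obj).__name__, **{k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_ensemble(path: str | Path, ens: ImagingEnsemble) -> None:
    with h5py.File(path, "w") as f:
        # track_times=False keeps files bit-identical across runs of one seed
        f.create_dataset("images", data=ens.images, dtype="f4", track_times=False)
        f.create_dataset("labels", data=ens.labels, dtype="i1", track_times=False)
        if ens.clean is not None:
            f.create_dataset("clean", data=ens.clean, dtype="f4", track_times=False)
        f.attrs["resolution_class"] = ens.resolution_class
        f.attrs["post_noise"] = ens.post_noise
        f.attrs["generation_spec"] = json.dumps(_jsonify(ens.generation_spec))
        if ens.noise_spec is not None:
            f.attrs["noise_spec"] = json.dumps(dataclasses.asdict(ens.noise_spec))


def load_ensemble(path: str | Path) -> ImagingEnsemble:
    with h5py.File(path, "r") as f:
        noise = None
        if "noise_spec" in f.attrs:
            noise = NoiseSpec(**json.loads(f.attrs["noise_spec"]))
        return ImagingEnsemble(
            f["images"][...],
            f["labels"][...],
            str(f.attrs["resolution_class"]),
            json.loads(f.attrs["generation_spec"]),
            f["clean"][...] if "clean" in f else None,
            str(f.attrs["post_noise"]),
            noise,
        )


def export_png(img: ObjectImage | np.ndarray, path: str | Path) -> tuple[float, float]:
    """Write a min-max scaled 8-bit PNG; the (lo, hi) scale is returned and
    recorded in the PNG text metadata."""
    x = np.asarray(img.pixels if isinstance(img, ObjectImage) else img, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    scaled = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    meta = PngInfo()
    meta.add_text("iqtask_scale_lo", repr(lo))
    meta.add_text("iqtask_scale_hi", repr(hi))
    Image.fromarray((scaled * 255).round().astype(np.uint8)).save(path, pnginfo=meta)
    return lo, hi


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class DatasetManifest:
    files: dict[str, dict] = field(default_factory=dict)  # relpath -> {sha256, bytes}
    specs: dict = field(default_factory=dict)
    created: str = ""
    code_version: str = iqtask.__version__

    def add(self, base_dir: Path, path: Path, spec: dict | None = None) -> None:
        rel = str(path.relative_to(base_dir))
        self.files[rel] = {"sha256": _sha256(path), "bytes": path.stat().st_size}
        if spec is not None:
            self.specs[rel] = _jsonify(spec)

    def save(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["created"] = payload["created"] or datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["files"], d.get("specs", {}), d.get("created", ""), d.get("code_version", ""))

    def verify(self, base_dir: str | Path) -> list[str]:
        """Return the list of files whose content no longer matches the manifest."""
        base = Path(base_dir)
        bad = []
        for rel, entry in self.files.items():
            p = base / rel
            if not p.exists() or _sha256(p) != entry["sha256"]:
                bad.append(rel)
        return bad


_FIXTURE_SIZES = {"tiny": (32, 64), "small": (64, 128)}


def make_fixtures(size: str, seed: int, out_dir: str | Path) -> DatasetManifest:
    """Write deterministic miniature HR/LR ensembles for both tasks plus a manifest."""
    if size not in _FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(_FIXTURE_SIZES)}")
    n_per_class, fieldsize = _FIXTURE_SIZES[size]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest()
    from iqtask.config import MC_CLB_AMPLITUDE, RAYLEIGH_CLB_AMPLITUDE

    for task, amp in (("rayleigh", RAYLEIGH_CLB_AMPLITUDE), ("mc", MC_CLB_AMPLITUDE)):
        clb = CLBParams(field_size=fieldsize, amplitude=amp)
        mc_spec = MCClusterSpec() if task == "mc" else None
        rng = stream_rng(seed, "clb" if task == "rayleigh" else "mc")
        hr, lr = build_task_ensembles(
            task, n_per_class, rng, clb=clb, mc_spec=mc_spec, keep_clean=True
        )
        for ens, tag in ((hr, "hr"), (lr, "lr")):
            path = out / f"{task}_{tag}_{size}.h5"
            save_ensemble(path, ens)
            manifest.add(out, path, {"task": task, "n_per_class": n_per_class, "seed": seed})
    manifest.save(out / "manifest.json")
    return manifest
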