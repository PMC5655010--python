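"""File I/O and voxel-wise orchestration.

Reads NIfTI 4-D volumes with FSL-style bvals/bvecs text files, runs the
per-voxel single-tensor fit independently for every masked voxel, and
assembles posterior mean/sd maps of FA and MD (plus optional variance-side
inclusion-probability maps).  Per-voxel seeds are derived deterministically
from the global seed and the voxel's row-major index, so serial and
parallel runs produce identical maps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .dti import AcquisitionScheme, fit_voxel
from .noise_models import NoiseModel
from .sampler import MCMCConfig

logger = logging.getLogger(__name__)

__all__ = ["VolumeJob", "MapSet", "read_bvals_bvecs", "load_dwi", "fit_volume",
           "save_mapset", "voxel_seed"]


@dataclass
class VolumeJob:
    """A validated volume-fitting task."""

    data: np.ndarray              # X x Y x Z x n
    scheme: AcquisitionScheme
    model: NoiseModel
    cfg: MCMCConfig
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    heteroscedastic: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI volume must be 4-D")
        if self.data.shape[3] != self.scheme.n:
            raise ValueError(
                f"volume has {self.data.shape[3]} measurements but the scheme has {self.scheme.n}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask grid does not match the volume grid")


@dataclass
class MapSet:
    """Per-voxel posterior summary volumes."""

    fa_mean: np.ndarray
    fa_sd: np.ndarray
    md_mean: np.ndarray
    md_sd: np.ndarray
    mask: np.ndarray
    inclusion_alpha: np.ndarray | None = None   # X x Y x Z x q
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def ratio_to(self, other: "MapSet") -> dict:
        """Voxelwise posterior-mean ratio maps (self / other) inside the
        joint mask."""
        joint = self.mask & other.mask
        out = {}
        for name in ("fa_mean", "md_mean", "fa_sd", "md_sd"):
            a, b = getattr(self, name), getattr(other, name)
            r = np.full_like(a, np.nan)
            ok = joint & (b != 0) & np.isfinite(a) & np.isfinite(b)
            r[ok] = a[ok] / b[ok]
            out[name] = r
        return out


def read_bvals_bvecs(bvals_path, bvecs_path):
    """FSL-style readers: bvals is one whitespace row, bvecs three rows
    (x, y, z).  Transposed layouts (n x 3 / n x 1) are auto-detected with a
    warning."""
    bvals = np.loadtxt(bvals_path, dtype=float)
    bvals = np.atleast_1d(bvals.squeeze()).ravel()
    bvecs = np.loadtxt(bvecs_path, dtype=float)
    if bvecs.ndim != 2:
        raise ValueError("bvecs must be a 2-D table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] == 3 and bvecs.shape[0] != 3:
        pass
    elif bvecs.shape == (3, 3):
        pass  # ambiguous; assume rows x/y/z already in FSL layout -> transpose
    else:
        raise ValueError(f"bvecs shape {bvecs.shape} has no axis of length 3")
    if bvecs.shape == (3, 3):
        bvecs = bvecs.T
        logger.warning("3x3 bvecs table is ambiguous; assuming FSL row layout")
    if len(bvals) != bvecs.shape[0]:
        raise ValueError(f"{len(bvals)} bvals but {bvecs.shape[0]} gradient vectors")
    return AcquisitionScheme(bvals, bvecs)


def load_dwi(volume_path, bvals_path, bvecs_path, mask_path=None,
             model: NoiseModel | None = None, cfg: MCMCConfig | None = None,
             heteroscedastic: bool = True) -> VolumeJob:
    """Load and validate a DWI fitting job from NIfTI + bvals/bvecs files."""
    img = nib.load(str(volume_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    scheme = read_bvals_bvecs(bvals_path, bvecs_path)
    mask = None
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.get_fdata()) > 0
    return VolumeJob(
        data=data, scheme=scheme,
        model=model or NoiseModel("rician"),
        cfg=cfg or MCMCConfig(),
        mask=mask, affine=np.asarray(img.affine),
        heteroscedastic=heteroscedastic,
    )


def voxel_seed(global_seed: int, index: int) -> int:
    """Deterministic per-voxel seed from the global seed and the voxel's
    row-major index (stable across serial/parallel execution orders)."""
    h = hashlib.sha256(f"{global_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _fit_one_voxel(args):
    """Top-level worker so process pools can pickle it; the per-voxel seed
    depends only on (global seed, row-major index), not execution order."""
    y, scheme, model, cfg_kwargs, heteroscedastic, ix = args
    try:
        draws = fit_voxel(y, scheme, model, MCMCConfig(**cfg_kwargs),
                          heteroscedastic=heteroscedastic)
    except Exception as exc:  # noqa: BLE001 - per-voxel failure is not fatal
        logger.warning("voxel %s failed: %s", ix, exc)
        return None
    fa, md = draws.extras["FA"], draws.extras["MD"]
    inc = draws.inclusion_probability_alpha() if draws.Ialpha.size else None
    return (float(fa.mean()), float(fa.std()), float(md.mean()), float(md.std()), inc)


def fit_volume(job: VolumeJob, n_jobs: int = 1) -> MapSet:
    """Fit every masked voxel independently and assemble summary maps.

    Per-voxel failures are logged and masked out rather than aborting the
    volume.  ``n_jobs > 1`` distributes voxels across processes without
    changing any seed, so parallel and serial runs are identical.
    """
    shape = job.data.shape[:3]
    idxs = [tuple(ix) for ix in np.argwhere(job.mask)]
    tasks = [
        (job.data[ix], job.scheme, job.model,
         {**job.cfg.__dict__,
          "seed": voxel_seed(job.cfg.seed, int(np.ravel_multi_index(ix, shape)))},
         job.heteroscedastic, ix)
        for ix in idxs
    ]
    if n_jobs > 1:
        from concurrent.futures import ProcessPoolExecutor
        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            results = list(pool.map(_fit_one_voxel, tasks))
    else:
        results = [_fit_one_voxel(t) for t in tasks]

    nan = np.full(shape, np.nan)
    out = MapSet(fa_mean=nan.copy(), fa_sd=nan.copy(), md_mean=nan.copy(),
                 md_sd=nan.copy(), mask=np.zeros(shape, dtype=bool),
                 affine=job.affine)
    q = 6 if job.heteroscedastic else 0
    if q:
        out.inclusion_alpha = np.full(shape + (q,), np.nan)
    for ix, res in zip(idxs, results):
        if res is None:
            continue
        out.mask[ix] = True
        out.fa_mean[ix], out.fa_sd[ix], out.md_mean[ix], out.md_sd[ix], inc = res
        if q and inc is not None:
            out.inclusion_alpha[ix] = inc
    out.meta = {
        "seed": job.cfg.seed,
        "model": job.model.family,
        "L": job.model.effective_L,
        "n_iter": job.cfg.n_iter,
        "n_burnin": job.cfg.n_burnin,
        "heteroscedastic": job.heteroscedastic,
        "config_hash": hashlib.sha256(
            json.dumps(job.cfg.__dict__, sort_keys=True).encode()).hexdigest()[:16],
    }
    return out


def save_mapset(maps: MapSet, outdir) -> None:
    """Write the summary volumes as NIfTI files plus a JSON provenance
    sidecar.  The input affine is passed through untouched."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("fa_mean", "fa_sd", "md_mean", "md_sd"):
        arr = getattr(maps, name)
        nib.save(nib.Nifti1Image(arr.astype(np.float64), maps.affine),
                 str(outdir / f"{name}.nii.gz"))
    nib.save(nib.Nifti1Image(maps.mask.astype(np.uint8), maps.affine),
             str(outdir / "mask.nii.gz"))
    if maps.inclusion_alpha is not None:
        nib.save(nib.Nifti1Image(maps.inclusion_alpha.astype(np.float64), maps.affine),
                 str(outdir / "inclusion_alpha.nii.gz"))
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(maps.meta, fh, indent=2)
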