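"""Synthetic paired FLAIR/DWI cohorts with known lesion ground truth.

Real multi-centre stroke cohorts are rarely redistributable, so this
module generates subjects whose structure matches the study setting:
an ellipse-based 2D head phantom stacked into 18-22 transverse slices,
tissue probability maps (WM/GM/CSF), chronic white matter lesions (WML)
hyperintense on FLAIR only, and, in a configurable fraction of
subjects, acute ischemic lesions (AIL) hyperintense on both DWI and
FLAIR. On FLAIR the AIL intensity is drawn from the same distribution
as WML, which is exactly what makes separating the two non-trivial for
a FLAIR-only segmenter.

WML load is placed with a periventricular preference inside the white
matter and its total volume is controlled exactly, so each subject
lands inside a requested severity stratum (mild <= 5 ml < moderate
<= 20 ml < severe). Pixel spacing is referenced to a 256 matrix and
scaled inversely with the simulated matrix size, keeping the head's
field of view constant; a severe lesion load therefore fits a 64 x 64
desk-scale grid just as it fits the full-resolution one.

Intensity model: piecewise-constant tissue means plus i.i.d. Gaussian
noise. Lesion-tissue contrast is kept at or above three noise standard
deviations so lesions remain learnable at any configured noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import InfeasibleSpecError, InvalidVolumeError
from .io import save_volume
from .preprocess import SubjectVolumes, TissueMaps

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "DEFAULT_SCORE_EDGES",
    "assign_true_score",
    "severity_stratum",
    "generate_subject",
    "generate_cohort",
]

STRATA = ("mild", "moderate", "severe")
# Target-volume sampling intervals per stratum (ml), kept clear of the
# 5/20 ml boundaries so voxel rounding cannot cross them.
_TARGET_ML = {"mild": (1.0, 4.5), "moderate": (6.0, 19.0), "severe": (21.0, 32.0)}

# Score thresholds: deciles of a log-spaced WMLV grid spanning 0-40 ml.
DEFAULT_SCORE_EDGES = np.geomspace(0.5, 40.0, 9)


def severity_stratum(wmlv_ml: float) -> str:
    """Mild (<= 5 ml), moderate (5-20 ml] or severe (> 20 ml)."""
    if wmlv_ml <= 5.0:
        return "mild"
    if wmlv_ml <= 20.0:
        return "moderate"
    return "severe"


def assign_true_score(wmlv_ml: float, score_map: np.ndarray = DEFAULT_SCORE_EDGES) -> int:
    """Map a WMLV to the 0-9 burden scale via a monotone step function.

    ``score_map`` holds the nine ascending lower edges of score bins
    1..9; the score is the number of edges the volume strictly exceeds.
    """
    if wmlv_ml < 0:
        raise InvalidVolumeError(f"negative WMLV {wmlv_ml}")
    edges = np.asarray(score_map, dtype=float)
    if edges.size != 9 or np.any(np.diff(edges) <= 0):
        raise ValueError("score_map must hold 9 strictly ascending edges")
    return int(np.sum(wmlv_ml > edges))


@dataclass
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    ``pixel_spacing_range`` (mm) refers to a 256 in-plane matrix; the
    sampled value is scaled by 256 / matrix_size so the field of view
    is independent of the simulated resolution.
    """

    n_subjects: int = 30
    ail_fraction: float = 0.47
    severity_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    slice_count_range: tuple[int, int] = (18, 22)
    matrix_size: int = 256
    pixel_spacing_range: tuple[float, float] = (0.43, 0.49)
    slice_thickness_range: tuple[float, float] = (5.0, 7.0)
    noise_sd: float = 10.0
    ail_volume_range_ml: tuple[float, float] = (0.5, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if not 0.0 <= self.ail_fraction <= 1.0:
            raise ValueError("ail_fraction must lie in [0, 1]")
        mix = np.asarray(self.severity_mix, dtype=float)
        if mix.size != 3 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("severity_mix must be 3 non-negative proportions summing to 1")
        for name in ("slice_count_range", "pixel_spacing_range", "slice_thickness_range", "ail_volume_range_ml"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must have lower <= upper")
        if self.matrix_size < 16:
            raise ValueError("matrix_size must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class SyntheticSubject:
    volumes: SubjectVolumes
    wml_truth: np.ndarray
    ail_truth: np.ndarray
    tissue: TissueMaps
    true_wmlv: float
    true_score: int
    stratum: str

    @property
    def subject_id(self) -> str:
        return self.volumes.subject_id


def _phantom(n_slices: int, side: int):
    """Boolean brain/WM/GM/CSF region stacks for the head phantom."""
    rows = np.arange(side)[:, None] - (side - 1) / 2
    cols = np.arange(side)[None, :] - (side - 1) / 2
    brain = np.zeros((n_slices, side, side), dtype=bool)
    gm = np.zeros_like(brain)
    csf = np.zeros_like(brain)
    zc = (n_slices - 1) / 2
    zr = max(n_slices / 2 - 1.0, 1.0)
    for z in range(n_slices):
        s2 = 1.0 - ((z - zc) / zr) ** 2
        if s2 <= 0.05:
            continue
        s = np.sqrt(s2)
        a, b = 0.42 * side * s, 0.36 * side * s
        r = np.sqrt((rows / a) ** 2 + (cols / b) ** 2)
        brain[z] = r <= 1.0
        gm[z] = (r > 0.82) & (r <= 1.0)
        if s > 0.45:
            for off in (-0.075, 0.075):
                va, vb = 0.14 * side * s, 0.05 * side * s
                vr = (rows / va) ** 2 + ((cols - off * side) / vb) ** 2
                csf[z] |= vr <= 1.0
    csf &= brain
    wm = brain & ~gm & ~csf
    return brain, wm, gm, csf


def _tissue_maps(brain, wm, gm, csf) -> TissueMaps:
    def prob(region):
        p = np.full(region.shape, 0.0, dtype=np.float32)
        p[brain] = 0.02
        p[region] = 0.95
        return p

    return TissueMaps(wm=prob(wm), gm=prob(gm), csf=prob(csf))


def _grow_lesions(
    candidates: np.ndarray,
    target_voxels: int,
    weight: np.ndarray,
    rng: np.random.Generator,
    radius_range: tuple[float, float],
) -> np.ndarray:
    """Greedy blob placement hitting ``target_voxels`` exactly.

    Blobs are in-plane disks (optionally spanning two slices) seeded at
    candidate voxels sampled with the given weighting; the last blob is
    trimmed farthest-voxels-first so the total voxel count is exact.
    """
    mask = np.zeros(candidates.shape, dtype=bool)
    cand_idx = np.nonzero(candidates)
    w = weight[cand_idx].astype(float)
    w /= w.sum()
    n_cand = len(cand_idx[0])
    side = candidates.shape[1]
    rows = np.arange(candidates.shape[1])[:, None]
    cols = np.arange(candidates.shape[2])[None, :]
    added = 0
    for _ in range(10_000):
        if added >= target_voxels:
            break
        k = rng.choice(n_cand, p=w)
        cz, cr, cc = cand_idx[0][k], cand_idx[1][k], cand_idx[2][k]
        radius = rng.uniform(*radius_range)
        span = [cz] if rng.random() < 0.5 or candidates.shape[0] == 1 else [cz, min(cz + 1, candidates.shape[0] - 1)]
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        disk = d2 <= radius**2
        for z in set(span):
            new = disk & candidates[z] & ~mask[z]
            need = target_voxels - added
            n_new = int(new.sum())
            if n_new == 0:
                continue
            if n_new > need:
                # trim farthest-first for a compact remainder
                rr, cc2 = np.nonzero(new)
                order = np.argsort(d2[rr, cc2], kind="stable")[:need]
                new = np.zeros_like(new)
                new[rr[order], cc2[order]] = True
                n_new = need
            mask[z] |= new
            added += n_new
    if added < target_voxels:
        raise InfeasibleSpecError(
            f"could not place {target_voxels} lesion voxels in {n_cand} candidate voxels"
        )
    return mask


def generate_subject(
    spec: CohortSpec,
    stratum: str,
    with_ail: bool,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
) -> SyntheticSubject:
    """One subject whose WML load falls inside the requested stratum."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum '{stratum}'")
    side = spec.matrix_size
    n_slices = int(rng.integers(spec.slice_count_range[0], spec.slice_count_range[1] + 1))
    spacing_base = rng.uniform(*spec.pixel_spacing_range)
    scale = 256.0 / side
    pixel_spacing = (spacing_base * scale, spacing_base * scale)
    thickness = float(rng.uniform(*spec.slice_thickness_range))
    voxel_ml = pixel_spacing[0] * pixel_spacing[1] * thickness / 1000.0

    brain, wm, gm, csf = _phantom(n_slices, side)
    tissue = _tissue_maps(brain, wm, gm, csf)

    # lesions must sit inside white matter, clear of the GM rim
    wm_core = ndimage.binary_erosion(wm, structure=np.ones((1, 3, 3), dtype=bool))
    dist_csf = np.stack([ndimage.distance_transform_edt(~csf[z]) for z in range(n_slices)])
    periv_weight = np.exp(-dist_csf / (0.10 * side)) + 0.15  # periventricular preference

    target_ml = float(rng.uniform(*_TARGET_ML[stratum]))
    target_vox = int(round(target_ml * 1000.0 / (voxel_ml * 1000.0)))
    target_vox = max(target_vox, 5)
    # severe disease may be confluent, but a load beyond ~80% of the
    # eroded white matter cannot be placed without losing lesion shape
    n_wm = int(wm_core.sum())
    if target_vox > 0.8 * n_wm:
        raise InfeasibleSpecError(
            f"stratum '{stratum}' needs {target_vox} voxels but only {n_wm} white-matter "
            f"voxels are available at matrix size {side}"
        )
    r_les = (max(1.5, side / 42), max(2.5, side / 16))
    wml = _grow_lesions(wm_core, target_vox, periv_weight, rng, r_les)

    ail = np.zeros_like(wml)
    if with_ail:
        ail_cand = wm_core & ~ndimage.binary_dilation(wml, structure=np.ones((1, 3, 3), dtype=bool))
        ail_ml = float(rng.uniform(*spec.ail_volume_range_ml))
        ail_vox = max(int(round(ail_ml / voxel_ml)), 5)
        ail = _grow_lesions(ail_cand, ail_vox, np.ones_like(periv_weight), rng, r_les)

    contrast = max(110.0, 3.0 * spec.noise_sd + 20.0)
    flair = np.zeros((n_slices, side, side), dtype=np.float32)
    flair[gm] = 110.0
    flair[wm] = 90.0
    flair[csf] = 30.0
    flair[wml] = 90.0 + contrast
    flair[ail] = 90.0 + contrast  # AIL mimics WML on FLAIR
    dwi = np.zeros_like(flair)
    dwi[brain] = 100.0
    dwi[csf] = 40.0
    dwi[ail] = 100.0 + contrast  # AIL bright on DWI; WML is not
    if spec.noise_sd > 0:
        flair = flair + rng.normal(0.0, spec.noise_sd, flair.shape).astype(np.float32)
        dwi = dwi + rng.normal(0.0, spec.noise_sd, dwi.shape).astype(np.float32)

    true_wmlv = float(wml.sum()) * voxel_ml
    volumes = SubjectVolumes(
        flair=flair, dwi=dwi, pixel_spacing=pixel_spacing, slice_thickness=thickness, subject_id=subject_id
    )
    return SyntheticSubject(
        volumes=volumes,
        wml_truth=wml,
        ail_truth=ail,
        tissue=tissue,
        true_wmlv=true_wmlv,
        true_score=assign_true_score(true_wmlv),
        stratum=stratum,
    )


def _stratum_counts(n: int, mix) -> dict[str, int]:
    """Largest-remainder apportionment of n subjects over the strata."""
    mix = np.asarray(mix, dtype=float)
    raw = mix * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(STRATA, counts.tolist()))


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """A cohort honouring ail_fraction and severity_mix within rounding.

    Returns the subjects and a manifest table; when ``out_dir`` is
    given, volumes and masks are written as NIfTI plus a manifest CSV
    and the spec as YAML.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _stratum_counts(spec.n_subjects, spec.severity_mix)
    strata = [s for s in STRATA for _ in range(counts[s])]
    n_ail = int(round(spec.n_subjects * spec.ail_fraction))
    ail_flags = np.zeros(spec.n_subjects, dtype=bool)
    if spec.n_subjects:
        ail_flags[rng.permutation(spec.n_subjects)[:n_ail]] = True

    subjects = []
    rows = []
    for i, (stratum, has_ail) in enumerate(zip(strata, ail_flags)):
        sid = f"sub-{i:03d}"
        subj = generate_subject(spec, stratum, bool(has_ail), rng, subject_id=sid)
        subjects.append(subj)
        rows.append(
            dict(
                id=sid,
                stratum=stratum,
                has_ail=bool(has_ail),
                true_wmlv_ml=subj.true_wmlv,
                true_score=subj.true_score,
            )
        )
    manifest = pd.DataFrame(rows, columns=["id", "stratum", "has_ail", "true_wmlv_ml", "true_score"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for subj in subjects:
            v = subj.volumes
            geom = dict(pixel_spacing=v.pixel_spacing, slice_thickness=v.slice_thickness)
            sid = v.subject_id
            save_volume(v.flair, out / f"{sid}_flair.nii.gz", **geom)
            save_volume(v.dwi, out / f"{sid}_dwi.nii.gz", **geom)
            save_volume(subj.wml_truth.astype(np.uint8), out / f"{sid}_wml.nii.gz", **geom)
            save_volume(subj.ail_truth.astype(np.uint8), out / f"{sid}_ail.nii.gz", **geom)
            save_volume(subj.tissue.wm, out / f"{sid}_wm.nii.gz", **geom)
            save_volume(subj.tissue.gm, out / f"{sid}_gm.nii.gz", **geom)
            save_volume(subj.tissue.csf, out / f"{sid}_csf.nii.gz", **geom)
        manifest.to_csv(out / "manifest.csv", index=False)
        spec.to_yaml(out / "cohort_spec.yaml")
    return subjects, manifest
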