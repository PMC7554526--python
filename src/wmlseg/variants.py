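"""The three experimental configurations: F, Cascade and FD.

* F: one network, FLAIR input, trained on WML ground truth.
* Cascade: the F network plus a second network segmenting acute
  ischemic lesions (AIL) from DWI; the final WML mask is the region
  called WML on FLAIR but not called AIL on DWI (set difference on the
  binarized masks).
* FD: one network with FLAIR and DWI stacked as a two-channel input,
  trained on WML ground truth only.

All variants in one comparison run share the train/test split, seeds,
epoch budget and augmentation stream, so differences in the outputs are
attributable to the input configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .augment import Augmenter
from .errors import AlignmentError, ConfigurationError, ModalityMissingError
from .model import NetConfig, UNetSegmenter
from .postprocess import filter_lesions, threshold_probabilities
from .preprocess import preprocess_subject

VARIANTS = ("F", "Cascade", "FD")

__all__ = [
    "VARIANTS",
    "VariantSpec",
    "PreparedSubject",
    "prepare_subject",
    "split_subjects",
    "cascade_combine",
    "VariantSegmenter",
    "run_variant",
    "VariantResult",
]


@dataclass(frozen=True)
class VariantSpec:
    """Network configuration bundle for one variant."""

    name: str
    wml_net: NetConfig
    ail_net: NetConfig | None = None

    def __post_init__(self):
        if self.name not in VARIANTS:
            raise ConfigurationError(f"variant must be one of {VARIANTS}, got '{self.name}'")
        want = 2 if self.name == "FD" else 1
        if self.wml_net.in_channels != want:
            raise ConfigurationError(f"{self.name} variant requires wml_net.in_channels == {want}")
        if (self.name == "Cascade") != (self.ail_net is not None):
            raise ConfigurationError("ail_net must be present exactly for the Cascade variant")
        if self.ail_net is not None and self.ail_net.in_channels != 1:
            raise ConfigurationError("the AIL network takes single-channel DWI input")

    @classmethod
    def default(cls, name: str, depth: int = 2, base_filters: int = 8) -> "VariantSpec":
        wml = NetConfig(2 if name == "FD" else 1, depth, base_filters)
        ail = NetConfig(1, depth, base_filters) if name == "Cascade" else None
        return cls(name, wml, ail)


@dataclass
class PreparedSubject:
    """A subject after preprocessing, ready for slice-wise training."""

    subject_id: str
    flair: np.ndarray  # (S, H, W), intensities in [0, 255]
    dwi: np.ndarray | None
    wml: np.ndarray  # binary, aligned
    ail: np.ndarray
    wm_prob: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    stratum: str = ""
    has_ail: bool = False
    true_wmlv: float = float("nan")
    true_score: int = -1
    kept_slices: list[int] | None = None  # indices into the native stack
    native_n_slices: int | None = None


def prepare_subject(subject, target_side: int | None = None, presence_threshold: float = 0.5) -> PreparedSubject:
    """Run the preprocessing chain on a synthetic (or loaded) subject."""
    side = target_side or subject.volumes.flair.shape[-1]
    vol, tissue, masks, kept = preprocess_subject(
        subject.volumes,
        subject.tissue,
        masks={"wml": subject.wml_truth, "ail": subject.ail_truth},
        target_side=side,
        presence_threshold=presence_threshold,
    )
    return PreparedSubject(
        subject_id=subject.volumes.subject_id,
        flair=vol.flair,
        dwi=vol.dwi,
        wml=masks["wml"].astype(bool),
        ail=masks["ail"].astype(bool),
        wm_prob=tissue.wm,
        pixel_spacing=vol.pixel_spacing,
        slice_thickness=vol.slice_thickness,
        stratum=getattr(subject, "stratum", ""),
        has_ail=bool(np.any(subject.ail_truth)),
        true_wmlv=getattr(subject, "true_wmlv", float("nan")),
        true_score=getattr(subject, "true_score", -1),
        kept_slices=kept,
        native_n_slices=subject.volumes.flair.shape[0],
    )


def split_subjects(subjects, test_fraction: float = 1 / 3, seed: int = 0):
    """Subject-level random split, stratified by severity and AIL status.

    The overall test-set size is round(test_fraction * n) (at least 1
    when the fraction is positive); it is apportioned over the
    (stratum, AIL) groups by largest remainder so small groups are
    represented fairly.
    """
    n = len(subjects)
    if n == 0:
        return [], []
    rng = np.random.default_rng(seed)
    n_test = min(n, int(round(test_fraction * n)))
    if test_fraction > 0:
        n_test = max(n_test, 1)
    groups: dict = {}
    for i, s in enumerate(subjects):
        groups.setdefault((s.stratum, s.has_ail), []).append(i)
    keys = sorted(groups, key=str)
    quotas = np.array([test_fraction * len(groups[k]) for k in keys])
    takes = np.floor(quotas).astype(int)
    remainders = quotas - takes
    for j in np.argsort(-remainders, kind="stable"):
        if takes.sum() >= n_test:
            break
        if takes[j] < len(groups[keys[j]]):
            takes[j] += 1
    test_idx = []
    for k, take in zip(keys, takes):
        idx = np.array(groups[k])
        rng.shuffle(idx)
        test_idx.extend(idx[:take].tolist())
    test_set = set(test_idx)
    train = [s for i, s in enumerate(subjects) if i not in test_set]
    test = [s for i, s in enumerate(subjects) if i in test_set]
    return train, test


def cascade_combine(wml_mask: np.ndarray, ail_mask: np.ndarray) -> np.ndarray:
    """Voxels identified as WML but not as AIL (set difference)."""
    wml_mask = np.asarray(wml_mask).astype(bool)
    ail_mask = np.asarray(ail_mask).astype(bool)
    if wml_mask.shape != ail_mask.shape:
        raise AlignmentError(f"mask shapes differ: {wml_mask.shape} vs {ail_mask.shape}")
    return wml_mask & ~ail_mask


def _stack_slices(subjects, channels: str):
    imgs, masks = [], []
    for s in subjects:
        if channels in ("dwi", "flair+dwi") and s.dwi is None:
            raise ModalityMissingError(f"subject {s.subject_id} has no DWI volume")
        if channels == "flair":
            x = s.flair[:, None]
            y = s.wml
        elif channels == "dwi":
            x = s.dwi[:, None]
            y = s.ail
        else:
            x = np.stack([s.flair, s.dwi], axis=1)
            y = s.wml
        imgs.append(x)
        masks.append(y)
    return np.concatenate(imgs), np.concatenate(masks).astype(np.float32)


class VariantSegmenter(BaseEstimator):
    """Sklearn-style estimator over prepared subjects for one variant.

    ``fit`` trains the variant's network(s) on the training subjects'
    slices; ``predict_proba`` returns per-subject probability volumes
    and ``predict`` binarized pre-filter candidate masks (with the
    cascade subtraction already applied for the Cascade variant).
    """

    def __init__(
        self,
        variant: str = "F",
        depth: int = 2,
        base_filters: int = 8,
        learning_rate: float = 0.01,
        batch_size: int = 4,
        epochs: int = 100,
        momentum: float = 0.9,
        seed: int = 0,
        augment: bool = True,
        tau: float = 0.5,
    ):
        self.variant = variant
        self.depth = depth
        self.base_filters = base_filters
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.momentum = momentum
        self.seed = seed
        self.augment = augment
        self.tau = tau

    def _net_kwargs(self):
        return dict(
            depth=self.depth,
            base_filters=self.base_filters,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            momentum=self.momentum,
        )

    def fit(self, subjects, y=None):
        spec = VariantSpec.default(self.variant, self.depth, self.base_filters)
        self.spec_ = spec
        self.loss_histories_ = {}
        ch = "flair+dwi" if self.variant == "FD" else "flair"
        X, ym = _stack_slices(subjects, ch)
        aug = Augmenter(seed=self.seed + 1) if self.augment else None
        wml = UNetSegmenter(
            in_channels=spec.wml_net.in_channels, seed=self.seed, augmenter=aug, **self._net_kwargs()
        )
        wml.fit(X, ym)
        self.wml_segmenter_ = wml
        self.loss_histories_["wml"] = wml.loss_history_
        self.ail_segmenter_ = None
        if self.variant == "Cascade":
            Xa, ya = _stack_slices(subjects, "dwi")
            aug_a = Augmenter(seed=self.seed + 1) if self.augment else None
            ail = UNetSegmenter(in_channels=1, seed=self.seed, augmenter=aug_a, **self._net_kwargs())
            ail.fit(Xa, ya)
            self.ail_segmenter_ = ail
            self.loss_histories_["ail"] = ail.loss_history_
        return self

    def predict_proba(self, subject: PreparedSubject) -> dict:
        if self.variant == "FD":
            if subject.dwi is None:
                raise ModalityMissingError(f"subject {subject.subject_id} has no DWI volume")
            x = np.stack([subject.flair, subject.dwi], axis=1)
        else:
            x = subject.flair[:, None]
        out = {"wml": self.wml_segmenter_.predict_proba(x)}
        if self.ail_segmenter_ is not None:
            if subject.dwi is None:
                raise ModalityMissingError(f"subject {subject.subject_id} has no DWI volume")
            out["ail"] = self.ail_segmenter_.predict_proba(subject.dwi[:, None])
        return out

    def predict(self, subject: PreparedSubject) -> np.ndarray:
        """Binarized candidate mask (cascade subtraction included)."""
        probs = self.predict_proba(subject)
        cand = threshold_probabilities(probs["wml"], self.tau)
        if "ail" in probs:
            cand = cascade_combine(cand, threshold_probabilities(probs["ail"], self.tau))
        return cand


@dataclass
class VariantResult:
    """Per-subject outputs of one variant run plus its run manifest."""

    name: str
    predictions: dict  # subject_id -> {"prob_wml", "prob_ail", "candidate", "final"}
    loss_histories: dict
    train_ids: list[str]
    test_ids: list[str]
    manifest: dict = field(default_factory=dict)


def run_variant(
    name: str,
    subjects: list[PreparedSubject],
    *,
    depth: int = 2,
    base_filters: int = 8,
    learning_rate: float = 0.01,
    batch_size: int = 4,
    epochs: int = 100,
    momentum: float = 0.9,
    seed: int = 0,
    augment: bool = True,
    tau: float = 0.5,
    min_pixels: int = 5,
    wm_tau: float = 0.4,
    test_fraction: float = 1 / 3,
    split: tuple[list, list] | None = None,
) -> VariantResult:
    """Train one variant and produce final masks for the test subjects.

    The split is subject-level and stratified; passing the same
    ``split`` (or the same seed) to every variant guarantees the
    comparison runs on identical data, seeds and epoch budget.
    """
    train, test = split if split is not None else split_subjects(subjects, test_fraction, seed)
    est = VariantSegmenter(
        variant=name,
        depth=depth,
        base_filters=base_filters,
        learning_rate=learning_rate,
        batch_size=batch_size,
        epochs=epochs,
        momentum=momentum,
        seed=seed,
        augment=augment,
        tau=tau,
    ).fit(train)
    predictions = {}
    for s in test:
        probs = est.predict_proba(s)
        cand = threshold_probabilities(probs["wml"], tau)
        if "ail" in probs:
            cand = cascade_combine(cand, threshold_probabilities(probs["ail"], tau))
        final = filter_lesions(cand, s.wm_prob, min_pixels=min_pixels, wm_tau=wm_tau)
        predictions[s.subject_id] = {
            "prob_wml": probs["wml"],
            "prob_ail": probs.get("ail"),
            "candidate": cand,
            "final": final,
        }
    manifest = dict(
        variant=name,
        depth=depth,
        base_filters=base_filters,
        learning_rate=learning_rate,
        batch_size=batch_size,
        epochs=epochs,
        momentum=momentum,
        seed=seed,
        augment=augment,
        tau=tau,
        min_pixels=min_pixels,
        wm_tau=wm_tau,
        train_ids=[s.subject_id for s in train],
        test_ids=[s.subject_id for s in test],
    )
    return VariantResult(
        name=name,
        predictions=predictions,
        loss_histories=est.loss_histories_,
        train_ids=manifest["train_ids"],
        test_ids=manifest["test_ids"],
        manifest=manifest,
    )
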