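"""True/false lumen classification with interchangeable backends.

A candidate void is only a *potential* lumen: enclosed dark regions also
arise from texture holes, debris pockets and noise.  Rather than fixing a
single deep model that would demand a large manually labeled corpus, the
classifier is an interface with four backends so the pipeline works at any
scale of available labels:

``trained``
    Gradient-boosted trees on rotation-invariant radial-profile features
    of the patch, trained on labeled patches (synthetic or user-provided).
``heuristic``
    A fixed, documented logistic score over three interpretable features
    (interior darkness, solidity, rim contrast); needs no training data.
``oracle``
    Looks up generator ground truth; used to isolate detection and
    reconstruction errors from classification errors in tests.
``constant``
    Returns a fixed probability; ``constant(1.0)`` accepts everything.

All backends return a probability of *true lumen* in [0, 1]; a candidate
is accepted iff the probability is >= ``decision_threshold`` (default 0.5).
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image, disk
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import train_test_split

from .detect2d import CandidateLumen2D
from .image_io import Calibration, FusedSlice
from .patch_prep import LumenPatch

logger = logging.getLogger(__name__)

TRUE_LUMEN = "true_lumen"
FALSE_LUMEN = "false_lumen"

_FORMAT = "lumenmetry-classifier"
_FORMAT_VERSION = 1

#: minimum fraction of candidate pixels inside a true void for the oracle
#: (and the training-set labeler) to call the candidate a true lumen.
ORACLE_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class LabeledPatch:
    patch: LumenPatch
    label: str

    def __post_init__(self) -> None:
        if self.label not in (TRUE_LUMEN, FALSE_LUMEN):
            raise ValueError(f"label must be {TRUE_LUMEN!r} or {FALSE_LUMEN!r}")

    @property
    def is_true(self) -> bool:
        return self.label == TRUE_LUMEN


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

_N_RADIAL_BINS = 10


def patch_features(pixels: np.ndarray) -> np.ndarray:
    """Rotation-invariant features of a patch.

    Radial mean-intensity profile (``_N_RADIAL_BINS`` annular bins from the
    patch center to the corner), plus center-disk mean, outer-ring mean,
    their contrast, and the global mean and standard deviation.  A true
    lumen shows a dark center and a bright ring; noise and rimless holes do
    not.
    """
    pixels = np.asarray(pixels, dtype=float)
    s = pixels.shape[0]
    yy, xx = np.mgrid[0:s, 0:s]
    c = (s - 1) / 2.0
    rho = np.hypot(yy - c, xx - c) / (s / 2.0)  # 0 center, 1 at edge midpoint
    bins = np.minimum((rho * _N_RADIAL_BINS).astype(int), _N_RADIAL_BINS - 1)
    profile = ndi.mean(pixels, labels=bins, index=np.arange(_N_RADIAL_BINS))
    center = float(pixels[rho <= 0.35].mean())
    ring = float(pixels[(rho > 0.55) & (rho <= 0.95)].mean())
    return np.concatenate(
        [profile, [center, ring, ring - center, pixels.mean(), pixels.std()]]
    )


def candidate_features(
    candidate: CandidateLumen2D,
    fused: FusedSlice,
    calibration: Calibration,
    rim_um: float = 5.0,
) -> tuple[float, float, float]:
    """(interior mean, solidity, rim contrast) measured on the fused slice.

    The rim is the ``rim_um``-wide dilation ring around the candidate
    mask; solidity is candidate area over its convex-hull area.
    """
    img = np.asarray(fused.raster, dtype=float)
    mask = candidate.mask
    interior = float(img[mask].mean())
    y0, x0, y1, x1 = candidate.bbox
    m = max(1, calibration.um_to_px(rim_um))
    y0e, x0e = max(0, y0 - m), max(0, x0 - m)
    y1e, x1e = min(mask.shape[0], y1 + m), min(mask.shape[1], x1 + m)
    local = mask[y0e:y1e, x0e:x1e]
    ring = ndi.binary_dilation(local, structure=disk(m).astype(bool)) & ~local
    rim_mean = float(img[y0e:y1e, x0e:x1e][ring].mean()) if ring.any() else interior
    hull = convex_hull_image(local)
    solidity = float(local.sum() / hull.sum()) if hull.any() else 1.0
    return interior, solidity, rim_mean - interior


def heuristic_score(interior_mean: float, solidity: float, rim_contrast: float) -> float:
    """Fixed logistic score of lumen-likeness.

    ``p = sigmoid(-4 + 2.5 * (1 - interior_mean) + 2 * solidity
    + 3 * clip(rim_contrast, -1, 1))``.  Darker interiors, more solid
    (convex) shapes and brighter rims all push toward "true lumen"; the
    intercept is set so that a contrast-free, ragged, bright-interior
    candidate scores well below 0.5 and an ideal dark solid rimmed void
    scores above 0.9.
    """
    z = (
        -4.0
        + 2.5 * (1.0 - float(interior_mean))
        + 2.0 * float(solidity)
        + 3.0 * float(np.clip(rim_contrast, -1.0, 1.0))
    )
    return float(1.0 / (1.0 + np.exp(-z)))


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class LumenClassifier:
    """Base interface; predictions are deterministic given the model state."""

    kind: str = "base"

    def __init__(self, decision_threshold: float = 0.5) -> None:
        if not (0.0 <= decision_threshold <= 1.0):
            raise ValueError("decision_threshold must be in [0, 1]")
        self.decision_threshold = decision_threshold

    def predict_proba(
        self,
        patch: LumenPatch,
        candidate: CandidateLumen2D | None = None,
        fused: FusedSlice | None = None,
        calibration: Calibration | None = None,
    ) -> float:
        raise NotImplementedError

    def accepts(self, patch, candidate=None, fused=None, calibration=None) -> bool:
        return self.predict_proba(patch, candidate, fused, calibration) >= self.decision_threshold

    # -- serialization ------------------------------------------------------
    def _state(self) -> dict:
        return {}

    def save(self, path: str | Path) -> None:
        blob = {
            "format": _FORMAT,
            "version": _FORMAT_VERSION,
            "kind": self.kind,
            "decision_threshold": self.decision_threshold,
            "state": self._state(),
        }
        with open(path, "wb") as fh:
            pickle.dump(blob, fh)

    @staticmethod
    def load(path: str | Path) -> "LumenClassifier":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if not isinstance(blob, dict) or blob.get("format") != _FORMAT:
            raise ValueError(f"{path}: not a {_FORMAT} file")
        if blob["version"] != _FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported format version {blob['version']}")
        cls = _KINDS[blob["kind"]]
        return cls._from_state(blob["state"], blob["decision_threshold"])

    @classmethod
    def _from_state(cls, state: dict, threshold: float) -> "LumenClassifier":
        raise NotImplementedError


class ConstantClassifier(LumenClassifier):
    """Returns a fixed probability for every candidate."""

    kind = "constant"

    def __init__(self, probability: float = 1.0, decision_threshold: float = 0.5) -> None:
        super().__init__(decision_threshold)
        self.probability = float(probability)

    def predict_proba(self, patch, candidate=None, fused=None, calibration=None) -> float:
        return self.probability

    def _state(self) -> dict:
        return {"probability": self.probability}

    @classmethod
    def _from_state(cls, state, threshold):
        return cls(state["probability"], threshold)


class OracleClassifier(LumenClassifier):
    """Ground-truth lookup: true iff the candidate lies mostly in a true void.

    ``true_masks`` is a ``(n_slices, H, W)`` boolean array marking the
    generator's true-lumen voxels.  Requires the candidate geometry.
    """

    kind = "oracle"

    def __init__(self, true_masks: np.ndarray, decision_threshold: float = 0.5) -> None:
        super().__init__(decision_threshold)
        self.true_masks = np.asarray(true_masks, dtype=bool)

    def predict_proba(self, patch, candidate=None, fused=None, calibration=None) -> float:
        if candidate is None:
            raise ValueError("oracle classifier requires the candidate geometry")
        gt = self.true_masks[candidate.z_index]
        n = candidate.n_pixels
        if n == 0:
            return 0.0
        frac = float((candidate.mask & gt).sum()) / n
        return 1.0 if frac >= ORACLE_OVERLAP_FRACTION else 0.0

    def _state(self) -> dict:
        return {"true_masks": np.packbits(self.true_masks), "shape": self.true_masks.shape}

    @classmethod
    def _from_state(cls, state, threshold):
        masks = np.unpackbits(state["true_masks"])[: int(np.prod(state["shape"]))]
        return cls(masks.reshape(state["shape"]).astype(bool), threshold)


class HeuristicClassifier(LumenClassifier):
    """Rule-based baseline applying :func:`heuristic_score`."""

    kind = "heuristic"

    def __init__(self, decision_threshold: float = 0.5, rim_um: float = 5.0) -> None:
        super().__init__(decision_threshold)
        self.rim_um = rim_um

    def predict_proba(self, patch, candidate=None, fused=None, calibration=None) -> float:
        if candidate is None or fused is None or calibration is None:
            raise ValueError("heuristic classifier requires candidate, fused slice and calibration")
        interior, solidity, contrast = candidate_features(
            candidate, fused, calibration, rim_um=self.rim_um
        )
        return heuristic_score(interior, solidity, contrast)

    def _state(self) -> dict:
        return {"rim_um": self.rim_um}

    @classmethod
    def _from_state(cls, state, threshold):
        return cls(threshold, state["rim_um"])


class TrainedClassifier(LumenClassifier):
    """Gradient-boosted trees over radial-profile patch features."""

    kind = "trained"

    def __init__(
        self,
        model: HistGradientBoostingClassifier,
        side: int,
        decision_threshold: float = 0.5,
        holdout_accuracy: float | None = None,
    ) -> None:
        super().__init__(decision_threshold)
        self.model = model
        self.side = side
        self.holdout_accuracy = holdout_accuracy

    def predict_proba(self, patch, candidate=None, fused=None, calibration=None) -> float:
        if patch.side != self.side:
            raise ValueError(f"patch side {patch.side} != classifier side {self.side}")
        x = patch_features(patch.pixels)[None, :]
        return float(self.model.predict_proba(x)[0, 1])

    def _state(self) -> dict:
        return {
            "model": self.model,
            "side": self.side,
            "holdout_accuracy": self.holdout_accuracy,
        }

    @classmethod
    def _from_state(cls, state, threshold):
        return cls(state["model"], state["side"], threshold, state["holdout_accuracy"])


_KINDS = {
    c.kind: c
    for c in (ConstantClassifier, OracleClassifier, HeuristicClassifier, TrainedClassifier)
}


def train(
    patches: list[LabeledPatch],
    seed: int,
    hyperparams: dict | None = None,
    decision_threshold: float = 0.5,
) -> TrainedClassifier:
    """Train the gradient-boosted backend on labeled patches.

    Requires at least two patches with both labels present.  An 80/20
    stratified split reports held-out accuracy in the training log and on
    the returned classifier (``holdout_accuracy``).  Reproducible given
    ``seed``.
    """
    if len(patches) < 2:
        raise ValueError("need at least 2 labeled patches")
    labels = np.array([int(p.is_true) for p in patches])
    if labels.min() == labels.max():
        raise ValueError("training set must contain both true_lumen and false_lumen labels")
    sides = {p.patch.side for p in patches}
    if len(sides) != 1:
        raise ValueError(f"patches have inconsistent sides {sides}")
    (side,) = sides

    X = np.stack([patch_features(p.patch.pixels) for p in patches])
    Xtr, Xte, ytr, yte = train_test_split(
        X, labels, test_size=0.2, random_state=seed, stratify=labels
    )
    params = {"max_iter": 200, "max_depth": 4, "learning_rate": 0.1}
    params.update(hyperparams or {})
    model = HistGradientBoostingClassifier(random_state=seed, **params)
    model.fit(Xtr, ytr)
    acc = float((model.predict(Xte) == yte).mean())
    logger.info(
        "trained lumen classifier on %d patches (held-out accuracy %.3f)", len(patches), acc
    )
    return TrainedClassifier(model, side, decision_threshold, holdout_accuracy=acc)


def load_labeled_patches(archive_dir, labels_csv) -> list[LabeledPatch]:
    """Join a patch archive with a ``candidate_id,label`` CSV.

    Labels may be the strings ``true_lumen`` / ``false_lumen`` or 1 / 0.
    Patches without a label row are skipped.
    """
    import pandas as pd

    from .patch_prep import load_patch_archive

    labels = pd.read_csv(labels_csv)
    if not {"candidate_id", "label"} <= set(labels.columns):
        raise ValueError("labels CSV must have candidate_id and label columns")
    mapping = {}
    for row in labels.itertuples():
        raw = row.label
        if isinstance(raw, str):
            label = raw.strip()
            if label not in (TRUE_LUMEN, FALSE_LUMEN):
                label = TRUE_LUMEN if int(label) else FALSE_LUMEN
        else:
            label = TRUE_LUMEN if int(raw) else FALSE_LUMEN
        mapping[row.candidate_id] = label
    return [
        LabeledPatch(patch, mapping[patch.candidate_id])
        for patch in load_patch_archive(archive_dir)
        if patch.candidate_id in mapping
    ]
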