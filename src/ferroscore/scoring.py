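"""PCA-based ferroptosis score: fit on training data, project via rotation.

Each signature (A = up in the case-enriched cluster, B = down) gets its own
PCA over its genes: the signature submatrix is centered gene-wise at the
training means and the leading loading vector (the *rotation*, unit norm
over genes) maps a centered sample profile to its PC1 coordinate. The raw
per-sample score is the difference of the two coordinates, coord_B -
coord_A, mirroring the gene-expression-grade-index construction; two sign
conventions then pin down the reported score:

* each rotation is flipped, if needed, so its coordinate rises with the
  mean expression of its own signature genes (PC sign ambiguity);
* a global orientation sign makes the case group score higher than the
  control group at training time (requires labels; +1 otherwise).

New cohorts are scored with the stored rotations and training means —
never refit — so the score is comparable across platforms that share the
gene identifier space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import ExpressionMatrix
from .diffexp import SignaturePair

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 3
_MAX_ABSENT_FRACTION = 0.5


@dataclass
class ScoringModel:
    """Serializable ferroptosis-score model: signature gene lists, training
    centering means, unit-norm PC1 rotations and the orientation sign."""

    signature_A: list[str]
    signature_B: list[str]
    gene_means_A: dict[str, float]
    gene_means_B: dict[str, float]
    rotation_A: dict[str, float]
    rotation_B: dict[str, float]
    orientation_sign: int = 1
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sig, rot, means in (
            ("A", self.signature_A, self.rotation_A, self.gene_means_A),
            ("B", self.signature_B, self.rotation_B, self.gene_means_B),
        ):
            if set(sig) != set(rot) or set(sig) != set(means):
                raise ValidationError(
                    f"signature {name} gene list does not index its rotation/means"
                )
            norm = float(np.linalg.norm(list(rot.values())))
            if abs(norm - 1.0) > 1e-10:
                raise ValidationError(f"rotation {name} is not unit norm ({norm})")
        if self.orientation_sign not in (1, -1):
            raise ValidationError("orientation_sign must be +1 or -1")

    def to_dict(self) -> dict:
        return {
            "signature_A": list(self.signature_A),
            "signature_B": list(self.signature_B),
            "gene_means_A": {g: float(v) for g, v in self.gene_means_A.items()},
            "gene_means_B": {g: float(v) for g, v in self.gene_means_B.items()},
            "rotation_A": {g: float(v) for g, v in self.rotation_A.items()},
            "rotation_B": {g: float(v) for g, v in self.rotation_B.items()},
            "orientation_sign": int(self.orientation_sign),
            "training_summary": dict(self.training_summary),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ScoringModel":
        return cls(
            signature_A=list(payload["signature_A"]),
            signature_B=list(payload["signature_B"]),
            gene_means_A=dict(payload["gene_means_A"]),
            gene_means_B=dict(payload["gene_means_B"]),
            rotation_A=dict(payload["rotation_A"]),
            rotation_B=dict(payload["rotation_B"]),
            orientation_sign=int(payload["orientation_sign"]),
            training_summary=dict(payload.get("training_summary", {})),
        )


def _fit_signature_pca(
    frame: pd.DataFrame,
    genes: list[str],
    name: str,
    min_genes: int,
    scale: bool,
) -> tuple[list[str], pd.Series, pd.Series, pd.Series]:
    """Return (used genes, training means, rotation, per-sample coords)."""
    present = [g for g in genes if g in frame.index]
    absent = [g for g in genes if g not in frame.index]
    if absent:
        logger.warning("signature %s: %d gene(s) absent from training matrix: %s",
                       name, len(absent), ", ".join(absent[:10]))
    if len(present) < min_genes:
        raise ValidationError(
            f"signature {name}: only {len(present)} usable gene(s), "
            f"need >= {min_genes}"
        )
    sub = frame.loc[present]
    means = sub.mean(axis=1)
    centered = sub.sub(means, axis=0)
    if scale:
        sds = sub.std(axis=1, ddof=1)
        if (sds == 0).any():
            raise ValidationError(f"signature {name}: zero-variance gene under scaling")
        centered = centered.div(sds, axis=0)
    if float(np.abs(centered.to_numpy()).max(initial=0.0)) == 0.0:
        raise ValidationError(f"signature {name}: zero-variance submatrix")
    # leading left-singular vector over genes = PC1 loading (rotation)
    u, s, _ = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    rotation = pd.Series(u[:, 0], index=present)
    coords = rotation @ centered
    # PC sign: coordinate should rise with mean signature expression
    sample_means = sub.mean(axis=0)
    anchor = float(np.dot(coords - coords.mean(), sample_means - sample_means.mean()))
    if anchor < 0:
        rotation = -rotation
        coords = -coords
    if scale:
        # fold 1/sd into the rotation so projection needs only means +
        # rotation; renormalizing rescales coordinates by one positive
        # constant per signature
        folded = rotation / sds
        norm = float(np.linalg.norm(folded))
        rotation = folded / norm
        coords = coords / norm
    return present, means, rotation, coords


def fit_score_model(
    matrix: ExpressionMatrix,
    signatures: SignaturePair,
    labels: pd.Series | dict | None = None,
    case_label: object = "TCMR",
    scale: bool = False,
    min_genes: int = DEFAULT_MIN_GENES,
) -> ScoringModel:
    """Fit the two-signature PCA score on a training matrix.

    ``labels`` (sample -> group), when given, fix the global orientation so
    the ``case_label`` group's mean training score exceeds the other
    group's; without labels the orientation defaults to +1 and a note is
    logged.
    """
    frame = matrix.to_frame()
    genes_A, means_A, rot_A, coords_A = _fit_signature_pca(
        frame, list(signatures.signature_A), "A", min_genes, scale)
    genes_B, means_B, rot_B, coords_B = _fit_signature_pca(
        frame, list(signatures.signature_B), "B", min_genes, scale)
    raw = coords_B - coords_A

    orientation = 1
    summary: dict = {"n_training_samples": matrix.n_samples,
                     "n_genes_A": len(genes_A), "n_genes_B": len(genes_B)}
    if labels is not None:
        lab = pd.Series(labels)
        case_ids = [s for s in matrix.sample_ids
                    if s in lab.index and lab[s] == case_label]
        other_ids = [s for s in matrix.sample_ids
                     if s in lab.index and lab[s] != case_label]
        if not case_ids or not other_ids:
            raise ValidationError(
                f"orientation needs both {case_label!r} and non-{case_label!r} samples"
            )
        if raw[case_ids].mean() < raw[other_ids].mean():
            orientation = -1
        summary["training_mean_score_case"] = float(orientation * raw[case_ids].mean())
        summary["training_mean_score_control"] = float(orientation * raw[other_ids].mean())
        summary["case_label"] = str(case_label)
    else:
        logger.info("no labels at fit time; orientation_sign defaults to +1")

    return ScoringModel(
        signature_A=genes_A, signature_B=genes_B,
        gene_means_A=means_A.to_dict(), gene_means_B=means_B.to_dict(),
        rotation_A=rot_A.to_dict(), rotation_B=rot_B.to_dict(),
        orientation_sign=orientation, training_summary=summary,
    )


def _project_signature(
    frame: pd.DataFrame,
    genes: list[str],
    means: dict[str, float],
    rotation: dict[str, float],
    name: str,
) -> pd.Series:
    present = [g for g in genes if g in frame.index]
    absent = [g for g in genes if g not in frame.index]
    if not present:
        raise ValidationError(f"signature {name}: no signature genes in new matrix")
    if len(absent) / len(genes) > _MAX_ABSENT_FRACTION:
        raise ValidationError(
            f"signature {name}: {len(absent)}/{len(genes)} genes absent "
            f"(> {_MAX_ABSENT_FRACTION:.0%}); projection unreliable"
        )
    if absent:
        logger.warning("signature %s: imputing %d absent gene(s) at training mean: %s",
                       name, len(absent), ", ".join(absent[:10]))
    coords = pd.Series(0.0, index=frame.columns)
    for g in present:
        centered = frame.loc[g] - means[g]
        # NaN cells are unmeasured values: impute at the training mean,
        # which contributes exactly 0 after centering
        coords = coords + rotation[g] * centered.fillna(0.0)
    return coords


def project_scores(model: ScoringModel, matrix: ExpressionMatrix) -> pd.Series:
    """Score new samples with the stored rotations and centering means.

    Returns a Series ``sample_id -> ferroptosis_score``. Genes absent from
    the new matrix (or NaN cells) sit at the training mean after centering
    and so contribute nothing; a sample with every signature value imputed
    scores exactly 0.
    """
    frame = matrix.to_frame()
    coords_A = _project_signature(frame, model.signature_A, model.gene_means_A,
                                  model.rotation_A, "A")
    coords_B = _project_signature(frame, model.signature_B, model.gene_means_B,
                                  model.rotation_B, "B")
    scores = model.orientation_sign * (coords_B - coords_A)
    scores.name = "ferroptosis_score"
    return scores


def write_scores(scores: pd.Series, path) -> None:
    frame = scores.rename("ferroptosis_score").rename_axis("sample_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    if not {"sample_id", "ferroptosis_score"} <= set(frame.columns):
        raise ValidationError(f"{path}: required columns sample_id, ferroptosis_score")
    return frame.set_index("sample_id")["ferroptosis_score"]
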