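"""Rigid-body backbone superposition and model-confidence summaries.

Used to validate a predicted receptor structure against a crystal
structure: backbone atoms (N, CA, C, O) are paired between the two
structures, superposed by the Kabsch least-squares algorithm (proper
rotations only, reflections excluded) and scored by RMSD. Predicted-model
confidence (pLDDT, stored in the B-factor column by convention) is
summarised into the standard very-high (> 90) and high (70, 90] bins.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegeneracyError, ValidationError
from .trajectory import Frame

__all__ = [
    "BACKBONE_ATOMS",
    "StructurePair",
    "SuperpositionResult",
    "ConfidenceSummary",
    "KabschAligner",
    "build_atom_map",
    "kabsch_superpose",
    "plddt_summary",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class StructurePair:
    """Two structures plus an ordered backbone atom correspondence."""

    mobile: Frame
    reference: Frame
    atom_map: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.atom_map) < 3:
            raise ValidationError(
                f"superposition needs >= 3 mapped atom pairs, got {len(self.atom_map)}")
        mob = [m for m, _ in self.atom_map]
        ref = [r for _, r in self.atom_map]
        if len(set(mob)) != len(mob) or len(set(ref)) != len(ref):
            raise ValidationError("atom map must be injective in both directions")

    @property
    def mobile_coords(self) -> np.ndarray:
        return np.array([self.mobile.atoms[m].position for m, _ in self.atom_map])

    @property
    def reference_coords(self) -> np.ndarray:
        return np.array([self.reference.atoms[r].position for _, r in self.atom_map])


@dataclass
class SuperpositionResult:
    """Optimal rigid transform (y ≈ R x + t) and the residual RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or not np.isclose(
                np.linalg.det(r), 1.0, atol=1e-8):
            raise ValidationError("rotation must be orthonormal with det +1")
        if self.rmsd < 0:
            raise ValidationError("rmsd must be non-negative")


@dataclass
class ConfidenceSummary:
    """Per-residue confidence fractions: pLDDT > 90 and 70 < pLDDT <= 90."""

    n_residues: int
    fraction_very_high: float
    fraction_high: float


def build_atom_map(mobile: Frame, reference: Frame,
                   pairing: str = "by_residue_number",
                   correspondence=None,
                   ca_only: bool = False) -> StructurePair:
    """Pair backbone atoms between two structures.

    ``by_residue_number`` pairs atoms with identical (chain, residue
    number, atom name); ``by_sequence_alignment_input`` consumes a
    caller-supplied residue correspondence — a CSV path or iterable of
    ``(mobile_resnum, reference_resnum)`` rows — and pairs backbone atoms
    within corresponding residues by atom name (chain-agnostic).
    """
    names = ("CA",) if ca_only else BACKBONE_ATOMS
    if pairing == "by_residue_number":
        ref_lookup = {
            (a.chain_id, a.residue_number, a.atom_name): i
            for i, a in enumerate(reference.atoms) if a.atom_name in names
        }
        atom_map = [
            (i, ref_lookup[(a.chain_id, a.residue_number, a.atom_name)])
            for i, a in enumerate(mobile.atoms)
            if a.atom_name in names
            and (a.chain_id, a.residue_number, a.atom_name) in ref_lookup
        ]
    elif pairing == "by_sequence_alignment_input":
        if correspondence is None:
            raise ValidationError(
                "pairing 'by_sequence_alignment_input' needs a residue "
                "correspondence table")
        if isinstance(correspondence, (str,)) or hasattr(correspondence, "read"):
            rows = []
            fh = open(correspondence) if isinstance(correspondence, str) else correspondence
            with fh:
                for row in csv.reader(fh):
                    if not row or row[0].strip().lower() == "mobile_resnum":
                        continue
                    rows.append((int(row[0]), int(row[1])))
        else:
            rows = [(int(m), int(r)) for m, r in correspondence]
        resmap = dict(rows)
        ref_lookup = {
            (a.residue_number, a.atom_name): i
            for i, a in enumerate(reference.atoms) if a.atom_name in names
        }
        atom_map = [
            (i, ref_lookup[(resmap[a.residue_number], a.atom_name)])
            for i, a in enumerate(mobile.atoms)
            if a.atom_name in names and a.residue_number in resmap
            and (resmap[a.residue_number], a.atom_name) in ref_lookup
        ]
    else:
        raise ValidationError(f"unknown pairing mode {pairing!r}")
    if len(atom_map) < 3:
        raise ValidationError(
            f"atom pairing produced only {len(atom_map)} pairs (< 3); "
            "check residue numbering or supply a correspondence table")
    return StructurePair(mobile=mobile, reference=reference, atom_map=atom_map)


class KabschAligner(BaseEstimator, TransformerMixin):
    """Least-squares rigid superposition of paired point sets.

    ``fit(X, Y)`` finds the proper rotation ``rotation_`` and translation
    ``translation_`` minimising the RMSD of ``R X + t`` against ``Y``
    (Kabsch algorithm via SVD, with the determinant correction that
    excludes reflections); ``transform(X)`` applies the fitted transform.

    Fitted attributes: ``rotation_`` (3×3, det +1), ``translation_``
    (3-vector, Å), ``rmsd_`` (Å).
    """

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
            raise ValidationError("fit needs matched (n >= 3, 3) coordinate arrays")
        xc, yc = X.mean(axis=0), Y.mean(axis=0)
        Xc, Yc = X - xc, Y - yc
        H = Xc.T @ Yc
        U, S, Vt = np.linalg.svd(H)
        # Collinear (or fully degenerate) point sets leave the rotation
        # about the common axis undetermined.
        if S[1] <= 1e-10 * max(S[0], 1.0):
            raise DegeneracyError(
                "point sets are collinear; the optimal rotation is not unique")
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        self.rotation_ = R
        self.translation_ = yc - R @ xc
        resid = (Xc @ R.T) - Yc
        self.rmsd_ = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.rotation_.T + self.translation_


def kabsch_superpose(pair: StructurePair) -> SuperpositionResult:
    """Optimal rigid superposition of a paired structure set (RMSD in Å)."""
    aligner = KabschAligner().fit(pair.mobile_coords, pair.reference_coords)
    return SuperpositionResult(rotation=aligner.rotation_,
                               translation=aligner.translation_,
                               rmsd=aligner.rmsd_)


def plddt_summary(model: Frame) -> ConfidenceSummary:
    """Summarise per-residue pLDDT read from the B-factor column.

    Every residue must carry a confidence value in [0, 100] (the value of
    its first atom is used; predicted-model files store one value per
    residue). Bins are disjoint so the fractions can sum: very high is
    pLDDT > 90, high is 70 < pLDDT <= 90.
    """
    per_residue: dict[tuple, float] = {}
    for a in model.atoms:
        key = (a.chain_id, a.residue_number)
        if key in per_residue:
            continue
        if a.b_factor is None:
            raise ValidationError(
                f"residue {a.chain_id}{a.residue_number}: no confidence value "
                "in the B-factor column")
        if not 0.0 <= a.b_factor <= 100.0:
            raise ValidationError(
                f"residue {a.chain_id}{a.residue_number}: confidence "
                f"{a.b_factor} outside [0, 100]")
        per_residue[key] = a.b_factor
    vals = np.array(list(per_residue.values()))
    n = len(vals)
    return ConfidenceSummary(
        n_residues=n,
        fraction_very_high=float(np.mean(vals > 90.0)),
        fraction_high=float(np.mean((vals > 70.0) & (vals <= 90.0))),
    )
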