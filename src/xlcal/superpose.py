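"""Rigid-body superposition and RMSD, with and without iterative outlier rejection.

Two reporting conventions coexist in model-comparison practice and both are
supported: a single least-squares (Kabsch) pass over all paired atoms ("no
outlier rejection"), and iterative refinement that drops pairs whose
residual exceeds a sigma cutoff and re-superposes — the convention behind
"with refinement" RMSDs, which can only shrink the fitted set's residual.

Residue pairing between models of different constructs (full-length vs
truncated) uses Needleman–Wunsch global alignment of the extracted
sequences; only aligned, non-gap positions with the required atoms present
contribute coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .structure import StructureModel

__all__ = ["SuperpositionResult", "kabsch", "pair_residues", "align_models"]

# Pairing alignment constants: identity scoring, gap open 10, extend 0.5.
# Only the pairing topology is consumed, never the scores.
_GAP_OPEN = -10.0
_GAP_EXTEND = -0.5


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_pairs_used: int
    n_pairs_rejected: int = 0
    cycles_run: int = 0
    rejected_pairs: list = field(default_factory=list)
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) coordinate array with the fitted rotation + translation."""
        return coords @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of b onto a.

    Reflections are excluded by construction (determinant correction on the
    SVD). Collinear/degenerate inputs are flagged, not rejected: the
    returned transform is still a valid least-squares solution.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"superposition requires at least 3 pairs, got {n}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    a0, b0 = a - cen_a, b - cen_b
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # second-smallest singular value ~0 => points are effectively collinear
    degenerate = bool(s[1] < 1e-8 * max(s[0], 1.0))
    translation = cen_a - rot @ cen_b
    resid = a - (b @ rot.T + translation)
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SuperpositionResult(
        rotation=rot, translation=translation, rmsd=rmsd,
        n_pairs_used=n, degenerate=degenerate,
    )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = _GAP_OPEN
    aligner.extend_gap_score = _GAP_EXTEND
    return aligner


def _chain_pairs(model_a: StructureModel, model_b: StructureModel) -> list[tuple[str, str]]:
    common = [c for c in model_a.chains if c in model_b.chains]
    if common:
        return [(c, c) for c in common]
    return list(zip(model_a.chains, model_b.chains))


def pair_residues(
    model_a: StructureModel,
    model_b: StructureModel,
    mode: str = "calpha",
) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Pair atoms between two models via global sequence alignment.

    Chains sharing an id are aligned with each other (otherwise chains pair
    in order). ``mode="calpha"`` pairs one Cα per aligned residue;
    ``mode="all_atom"`` pairs identically-named atoms within aligned
    residues, so a residue modelled without its side chain contributes
    backbone atoms only.

    Returns (coords_a, coords_b, pairing) where pairing holds
    (residue_id_a, residue_id_b, atom_name) triples.
    """
    if mode not in {"calpha", "all_atom"}:
        raise ValueError(f"unknown pairing mode {mode!r}")
    aligner = _aligner()
    xyz_a: list[np.ndarray] = []
    xyz_b: list[np.ndarray] = []
    pairing: list[tuple] = []
    for cid_a, cid_b in _chain_pairs(model_a, model_b):
        res_a = model_a.chains[cid_a]
        res_b = model_b.chains[cid_b]
        seq_a = model_a.chain_sequence(cid_a)
        seq_b = model_b.chain_sequence(cid_b)
        alignment = aligner.align(seq_a, seq_b)[0]
        for (sa, ea), (sb, _eb) in zip(*alignment.aligned):
            for off in range(ea - sa):
                ra, rb = res_a[sa + off], res_b[sb + off]
                if mode == "calpha":
                    names = ["CA"]
                else:
                    names = sorted(
                        {at.name for at in ra.atoms} & {at.name for at in rb.atoms}
                    )
                for name in names:
                    at_a, at_b = ra.get(name), rb.get(name)
                    if at_a is None or at_b is None:
                        continue
                    xyz_a.append(at_a.coords)
                    xyz_b.append(at_b.coords)
                    pairing.append((ra.id, rb.id, name))
    if not pairing:
        raise ValueError("no pairable residues between the two models")
    return np.array(xyz_a), np.array(xyz_b), pairing


def align_models(
    model_a: StructureModel,
    model_b: StructureModel,
    mode: str = "calpha",
    refine: Optional[tuple[float, int]] = None,
    rmsd_atoms: Optional[str] = None,
) -> SuperpositionResult:
    """Superpose model_b onto model_a and report RMSD.

    ``refine=None`` is a single Kabsch pass over all pairs.
    ``refine=(cutoff_sigma, max_cycles)`` iterates: superpose, drop pairs
    with residual > cutoff_sigma x residual standard deviation, re-superpose;
    stops when no pair is dropped or max_cycles is reached. The RMSD covers
    surviving pairs, with full rejection bookkeeping.

    ``rmsd_atoms`` optionally reports the RMSD over a different atom set
    than the one fitted — e.g. fit on Cα pairs, report all-atom RMSD
    (``mode="calpha", rmsd_atoms="all_atom"``), the common two-stage
    convention for comparing refined models.
    """
    a, b, pairing = pair_residues(model_a, model_b, mode)
    keep = np.ones(len(pairing), dtype=bool)
    cycles = 0
    if refine is None:
        result = kabsch(a, b)
    else:
        cutoff_sigma, max_cycles = refine
        result = kabsch(a, b)
        while cycles < max_cycles:
            resid = np.linalg.norm(a[keep] - result.apply(b[keep]), axis=1)
            # sigma = RMS residual (std of the coordinate deviations), the
            # conventional rejection scale for superposition refinement
            sigma = float(np.sqrt(np.mean(resid**2)))
            # converged: residual spread at numerical noise level
            if sigma < 1e-8 or resid.max() < 1e-8:
                break
            drop_local = resid > cutoff_sigma * sigma
            if not drop_local.any():
                break
            kept_idx = np.flatnonzero(keep)
            keep[kept_idx[drop_local]] = False
            cycles += 1
            if keep.sum() < 3:
                raise ValueError(
                    "outlier rejection removed too many pairs (cutoff too aggressive)"
                )
            result = kabsch(a[keep], b[keep])
    rejected = [pairing[i] for i in np.flatnonzero(~keep)]
    out = SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_pairs_used=int(keep.sum()),
        n_pairs_rejected=int((~keep).sum()),
        cycles_run=cycles,
        rejected_pairs=rejected,
        degenerate=result.degenerate,
    )
    if rmsd_atoms is not None and rmsd_atoms != mode:
        ra, rb, _ = pair_residues(model_a, model_b, rmsd_atoms)
        resid = ra - out.apply(rb)
        out.rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return out
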