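"""Deterministic synthetic fixtures for every input class of the toolkit.

Generators here stand in for externally produced inputs — predicted
structure models, docking decoy sets, search-engine crosslink tables and
instrument sensorgrams — so the full pipeline is exercisable offline. Every
generator is a pure function of its arguments plus a seed (byte-identical
reruns) and fixtures never claim chemical realism: helices are ideal
backbones and the pseudo-NZ is a fixed 6.4 Å outward offset from Cα, a
documented geometric stand-in for a lysine side chain.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .restraints import RestraintPolicy
from .spr import KineticParams, Sensorgram, simulate_1to1
from .structure import Atom, Residue, StructureModel

__all__ = [
    "make_helix_model",
    "make_decoys",
    "rigid_transform",
    "make_crosslink_table",
    "make_sensorgram_set",
    "sensorgrams_to_csv",
    "sensorgrams_from_csv",
    "lobster_model",
]

# ideal alpha-helix parameters: 1.5 Å rise, 100 deg/residue, Ca radius 2.3 Å
_RISE = 1.5
_TWIST = math.radians(100.0)
_R_CA = 2.3
_NZ_OFFSET = 6.4  # pseudo side-chain NZ, Å outward from Ca

# backbone atom placement (radius, phase offset rad, z offset) — approximate
_BACKBONE = {
    "N": (1.55, math.radians(-28.0), -0.90),
    "CA": (_R_CA, 0.0, 0.0),
    "C": (2.00, math.radians(27.0), 0.42),
}


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z to the given axis (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def make_helix_model(
    length: int,
    chain_id: str = "A",
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    lysines: Optional[Sequence[int]] = None,
    start_seq: int = 1,
    model_id: str = "helix",
    phase: float = 0.0,
) -> StructureModel:
    """Ideal α-helix backbone (N, CA, C) with pseudo-NZ atoms at lysines.

    ``lysines`` are 1-based positions along the helix (relative to its first
    residue); those residues become LYS with an NZ placed 6.4 Å radially
    outward from the Cα. Everything else is ALA. Deterministic.
    """
    if length < 4:
        raise ValueError("helix needs at least 4 residues")
    lys = {int(p) for p in (lysines or [])}
    rot = _rotation_to(np.asarray(axis, dtype=float))
    origin = np.asarray(origin, dtype=float)
    residues = []
    for i in range(length):
        ang = phase + _TWIST * i
        atoms = []
        for name, (radius, dphi, dz) in _BACKBONE.items():
            local = np.array(
                [radius * math.cos(ang + dphi), radius * math.sin(ang + dphi), _RISE * i + dz]
            )
            atoms.append(Atom(name=name, element=name[0], coords=rot @ local + origin))
        is_lys = (i + 1) in lys
        if is_lys:
            radial = np.array([math.cos(ang), math.sin(ang), 0.0])
            local = np.array(
                [_R_CA * math.cos(ang), _R_CA * math.sin(ang), _RISE * i]
            ) + _NZ_OFFSET * radial
            atoms.append(Atom(name="NZ", element="N", coords=rot @ local + origin))
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_number=start_seq + i,
                res_name="LYS" if is_lys else "ALA",
                atoms=atoms,
            )
        )
    return StructureModel(model_id=model_id, chains={chain_id: residues})


def merge_models(model_id: str, *models: StructureModel) -> StructureModel:
    """Combine single-chain models into one multi-chain model (distinct chain ids)."""
    chains = {}
    for m in models:
        for cid, residues in m.chains.items():
            if cid in chains:
                chains[cid] = chains[cid] + residues
            else:
                chains[cid] = list(residues)
    return StructureModel(model_id=model_id, chains=chains)


def rigid_transform(
    angle_deg: float = 0.0,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    translation: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """(rotation, translation) for a proper rigid motion."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = math.radians(angle_deg)
    vx = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + math.sin(theta) * vx + (1 - math.cos(theta)) * (vx @ vx)
    return rot, np.asarray(translation, dtype=float)


def make_decoys(
    model: StructureModel,
    transforms: Sequence[tuple[np.ndarray, np.ndarray]],
    chain_id: str,
) -> list[StructureModel]:
    """One decoy per rigid transform applied to the named chain.

    Transform 0 may be the identity, making decoy 0 the planted truth.
    """
    if chain_id not in model.chains:
        raise KeyError(f"chain {chain_id!r} not in model")
    decoys = []
    for k, (rot, trans) in enumerate(transforms):
        rot = np.asarray(rot, dtype=float)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) or np.linalg.det(rot) < 0:
            raise ValueError(f"transform {k} is not a proper rigid rotation")
        decoy = model.copy()
        decoy.model_id = f"{model.model_id}_decoy{k:03d}"
        for res in decoy.chains[chain_id]:
            for atom in res.atoms:
                atom.coords = rot @ atom.coords + trans
        decoys.append(decoy)
    return decoys


def _lysine_nz(model: StructureModel):
    out = []
    for res in model.residues():
        if res.res_name == "LYS":
            nz = res.get("NZ")
            if nz is not None:
                out.append((res, nz))
    return out


def make_crosslink_table(
    model: StructureModel,
    policy: RestraintPolicy = RestraintPolicy(),
    n_pairs: int = 14,
    psm_multiplicity: int = 3,
    seed: int = 0,
    kind: str = "intra",
    protein_of_chain: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """PSM-redundant crosslink table sampled from a model's reachable lysine pairs.

    Pairs are drawn among lysine NZ atoms whose distance satisfies the
    policy (``kind="intra"``: same chain, <= intra_max; ``kind="inter"``:
    different chains, within [inter_min, inter_max]); each pair is emitted
    ``psm_multiplicity`` times at varied charge states. Deterministic per seed.
    """
    protein_of_chain = protein_of_chain or {c: c for c in model.chains}
    sites = _lysine_nz(model)
    reachable = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            ra, aa = sites[i]
            rb, ab = sites[j]
            d = float(np.linalg.norm(aa.coords - ab.coords))
            same = ra.chain_id == rb.chain_id
            if kind == "intra" and same and d <= policy.intra_max:
                reachable.append((ra, rb))
            elif kind == "inter" and not same and policy.inter_min <= d <= policy.inter_max:
                reachable.append((ra, rb))
    if len(reachable) < n_pairs:
        raise ValueError(
            f"only {len(reachable)} lysine pairs reachable under the policy "
            f"(requested {n_pairs})"
        )
    rng = np.random.default_rng(seed)
    chosen = [reachable[i] for i in sorted(rng.choice(len(reachable), n_pairs, replace=False))]

    def peptide(res: Residue) -> str:
        seq = model.chain_sequence(res.chain_id)
        start = res.seq_number - model.chains[res.chain_id][0].seq_number
        return seq[max(0, start - 1): start + 4]

    rows = []
    psm = 0
    for ra, rb in chosen:
        for _ in range(psm_multiplicity):
            rows.append(
                {
                    "protein_a": protein_of_chain[ra.chain_id],
                    "peptide_a": peptide(ra),
                    "link_pos_a": ra.seq_number,
                    "protein_b": protein_of_chain[rb.chain_id],
                    "peptide_b": peptide(rb),
                    "link_pos_b": rb.seq_number,
                    "charge": int(rng.choice([2, 3, 4])),
                    "psm_id": f"psm{psm:05d}",
                    "score": round(float(rng.uniform(10, 100)), 2),
                    "qvalue": round(float(rng.uniform(0, 0.01)), 5),
                }
            )
            psm += 1
    return pd.DataFrame(rows)


def make_sensorgram_set(
    params: KineticParams,
    concentrations: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_assoc: float = 240.0,
    t_dissoc: float = 240.0,
    dt: float = 1.0,
) -> list[Sensorgram]:
    """Multi-concentration sensorgram set; default grid 0.1/0.3/1/3/10 x KD.

    The default five-point grid spans the typical 3–5 analyte concentrations
    of a KD titration; the dissociation window defaults to 4 minutes.
    """
    if concentrations is None:
        kd_molar = params.KD
        concentrations = [m * kd_molar for m in (0.1, 0.3, 1.0, 3.0, 10.0)]
    return [
        simulate_1to1(
            params, conc, t_assoc, t_dissoc, dt,
            noise_sd=noise_sd, seed=seed + i, label=f"conc_{i}",
        )
        for i, conc in enumerate(concentrations)
    ]


def sensorgrams_to_csv(curves: Sequence[Sensorgram], path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": c.time,
                    "response_RU": c.response,
                    "conc_M": c.analyte_conc,
                    "label": c.label,
                    "t_assoc_end_s": c.t_assoc_end,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def sensorgrams_from_csv(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    curves = []
    for label, group in df.groupby("label", sort=False):
        curves.append(
            Sensorgram(
                time=group["time_s"].to_numpy(),
                response=group["response_RU"].to_numpy(),
                analyte_conc=float(group["conc_M"].iloc[0]),
                t_assoc_end=float(group["t_assoc_end_s"].iloc[0]),
                label=str(label),
            )
        )
    return curves


def lobster_model(model_id: str = "lobster") -> StructureModel:
    """Canonical single-chain fixture: 4 major + 4 short helical segments.

    A compact helical-bundle topology with lysines every 4th residue on the
    major helices, giving well over 14 intra-chain lysine pairs within DSSO
    reach — the fixture used throughout the docs and tests. Deterministic.
    """
    segments = [
        # (length, origin, axis, lysine positions within segment)
        (32, (0.0, 0.0, 0.0), (0, 0, 1), (2, 6, 10, 14, 18, 22, 26, 30)),
        (32, (10.0, 0.0, 48.0), (0, 0, -1), (2, 6, 10, 14, 18, 22, 26, 30)),
        (32, (0.0, 10.0, 0.0), (0, 0, 1), (2, 6, 10, 14, 18, 22, 26, 30)),
        (32, (10.0, 10.0, 48.0), (0, 0, -1), (2, 6, 10, 14, 18, 22, 26, 30)),
        (8, (-10.0, 0.0, 0.0), (0, 0, 1), (4,)),
        (8, (-10.0, 10.0, 12.0), (0, 0, -1), (4,)),
        (8, (20.0, 0.0, 0.0), (0, 0, 1), (4,)),
        (8, (20.0, 10.0, 12.0), (0, 0, -1), (4,)),
    ]
    residues = []
    seq_no = 1
    for length, origin, axis, lys in segments:
        seg = make_helix_model(
            length, chain_id="A", origin=origin, axis=axis,
            lysines=lys, start_seq=seq_no,
        )
        residues.extend(seg.chains["A"])
        seq_no += length
    return StructureModel(model_id=model_id, chains={"A": residues})
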