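"""Synthetic recurrent RNA loop motifs and motif-library I/O.

Real model building draws loop motifs from curated fragment databases; this
package ships a small generator of *synthetic, idealized* stand-ins so that
every pipeline stage is testable without external downloads:

* a GNRA-type tetraloop (2-bp stem + 4 loop nucleotides),
* a sarcin-ricin-like loop (2-bp stem + 5 loop nucleotides),
* a symmetric internal loop (two strands, flanking pairs at both ends).

Loop nucleotides are placed with their phosphates on a smooth Bezier arc
that closes the strand with ~6 Å P-P spacing and bases pointing away from
the stem axis.  The same generator provides the planted ground truth for
the benchmark crystals, so recovery tests are exact by construction.

Motif libraries are directories of PDB fragments, each with a JSON sidecar
recording the flanking Watson-Crick pairs and base-pair annotations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .crystal_maps import AtomicModel
from .fiber import (
    BACKBONE,
    BASE_FRAME,
    FIBER_PARAMS,
    Motif,
    _PAIR_FLIP,
    _rz,
    complement,
    nucleotide_template,
)

__all__ = [
    "make_tetraloop",
    "make_sarcin_like_loop",
    "make_internal_loop",
    "default_library",
    "save_library",
    "load_library",
    "hairpin_motif",
]

_P_LOCAL = {n: np.array([x, y, z])
            for n, x, y, z in BACKBONE["A-RNA"]}["P"]


def _bezier(q0: np.ndarray, qc: np.ndarray, qe: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = t[:, None]
    return (1 - t) ** 2 * q0 + 2 * t * (1 - t) * qc + t**2 * qe


def _arc_points(q0: np.ndarray, qe: np.ndarray, bulge_dir: np.ndarray,
                n_points: int, spacing: float = 6.0) -> np.ndarray:
    """n_points along a Bezier arc from q0 towards qe, first point at q0,
    consecutive spacing ~= `spacing`, final gap to qe ~= `spacing`."""
    target_len = spacing * n_points
    bulge_dir = bulge_dir / np.linalg.norm(bulge_dir)
    mid = 0.5 * (q0 + qe)

    def arc(bulge: float) -> np.ndarray:
        dense = _bezier(q0, mid + bulge * bulge_dir, qe, np.linspace(0, 1, 400))
        return dense

    lo, hi = 0.0, 40.0
    for _ in range(60):  # bisection on the bulge magnitude for arc length
        b = 0.5 * (lo + hi)
        dense = arc(b)
        length = np.linalg.norm(np.diff(dense, axis=0), axis=1).sum()
        if length < target_len:
            lo = b
        else:
            hi = b
    dense = arc(0.5 * (lo + hi))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    # equal-arc-length stations: k * total/(n_points) for k = 0..n_points-1
    stations = cum[-1] * np.arange(n_points) / n_points
    out = np.empty((n_points, 3))
    for i, s in enumerate(stations):
        j = np.searchsorted(cum, s)
        j = min(max(j, 1), len(cum) - 1)
        w = (s - cum[j - 1]) / max(cum[j] - cum[j - 1], 1e-12)
        out[i] = dense[j - 1] * (1 - w) + dense[j] * w
    return out


_O3_LOCAL = {n: np.array([x, y, z]) for n, x, y, z in BACKBONE["A-RNA"]}["O3'"]
_BASE_CENTROID = np.array(
    [[x, y, z] for _n, x, y, z in BASE_FRAME["A"][1:]]).mean(axis=0)


def _axis_rotation(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(axis, axis)


def _loop_frames(points: np.ndarray, qe: np.ndarray) -> list[np.ndarray]:
    """Rotations placing loop nucleotides along the arc.

    Each rotation maps the nucleotide's own chain direction (P -> O3') onto
    the local arc tangent and its P -> base-centroid vector onto the outward
    radial, so bases fan away from the stem axis; alternating roll about the
    tangent keeps neighbouring bases from overlapping.
    """
    u1 = _O3_LOCAL - _P_LOCAL
    u1 = u1 / np.linalg.norm(u1)
    u2 = _BASE_CENTROID - _P_LOCAL
    u2 = u2 - u1 * (u2 @ u1)
    u2 = u2 / np.linalg.norm(u2)
    local = np.column_stack([u1, u2, np.cross(u1, u2)])
    frames = []
    ext = np.vstack([points, qe])
    for i in range(len(points)):
        ez = ext[i + 1] - ext[i]
        ez = ez / np.linalg.norm(ez)
        radial = np.array([points[i][0], points[i][1], 0.0])
        if np.linalg.norm(radial) < 1e-6:
            radial = np.array([1.0, 0.0, 0.0])
        ey = radial - ez * (radial @ ez)
        ey = ey / np.linalg.norm(ey)
        world = np.column_stack([ez, ey, np.cross(ez, ey)])
        roll = _axis_rotation(ez, 50.0 if i % 2 else -30.0)
        frames.append(roll @ world @ local.T)
    return frames


def _place_residue(rows: list, p_points: list, letter: str, R: np.ndarray,
                   t: np.ndarray, chain: str, resseq: int, with_p: bool) -> None:
    for name, local in nucleotide_template(letter, "A-RNA", with_p):
        pos = R @ local + t
        rows.append((name[0], name, letter, resseq, chain, tuple(pos), 20.0, 1.0))
        if name == "P":
            p_points.append(pos)


def hairpin_motif(loop_seq: str, stem_seq: str = "GC", bulge_dir=(1.0, 0.0, 0.6),
                  spacing: float = 6.0, tag: str = "hairpin") -> Motif:
    """Stem-loop motif: `len(stem_seq)`-bp A-form stem closed by a loop.

    Single chain S: stem ascending, loop on an arc, stem descending.  The
    flanking Watson-Crick pair is the outermost stem pair.
    """
    rise, twist = FIBER_PARAMS["A-RNA"]
    ns, nl = len(stem_seq), len(loop_seq)
    rows: list = []
    p_points: list = []
    res = 1
    # ascending stem strand
    for i in range(ns):
        _place_residue(rows, p_points, stem_seq[i], _rz(i * twist),
                       np.array([0.0, 0.0, i * rise]), "S", res, with_p=res > 1)
        res += 1
    # loop arc: from the helix-continuation P to the P of the descending
    # strand; the bulge direction is fixed relative to the innermost pair
    # frame so the loop shape is independent of the stem length
    q0 = _rz(ns * twist) @ _P_LOCAL + np.array([0.0, 0.0, ns * rise])
    R_desc_inner = _rz((ns - 1) * twist) @ _PAIR_FLIP
    qe = R_desc_inner @ _P_LOCAL + np.array([0.0, 0.0, (ns - 1) * rise])
    bulge = _rz((ns - 1) * twist) @ np.asarray(bulge_dir, float)
    arc = _arc_points(q0, qe, bulge, nl, spacing)
    frames = _loop_frames(arc, qe)
    for k in range(nl):
        R = frames[k]
        t = arc[k] - R @ _P_LOCAL
        _place_residue(rows, p_points, loop_seq[k], R, t, "S", res, with_p=True)
        res += 1
    # descending stem strand (pairs the ascending one, inner pair first)
    for j in range(ns):
        i = ns - 1 - j
        _place_residue(rows, p_points, complement(stem_seq[i], "A-RNA"),
                       _rz(i * twist) @ _PAIR_FLIP,
                       np.array([0.0, 0.0, i * rise]), "S", res, with_p=True)
        res += 1
    n_res = res - 1
    pairs = [(("S", 1 + i), ("S", n_res - i)) for i in range(ns)]
    annotations = [{"res_i": a, "res_j": b, "type": "WC"} for a, b in pairs]
    return Motif(
        fragment=AtomicModel.from_rows(rows),
        p_pattern=np.array(p_points),
        # the innermost stem pair is the attachment interface: superposing
        # it onto a stem terminal pair continues the helix into the loop
        flanking_pairs=[pairs[-1]],
        pair_annotations=annotations,
        tag=tag,
    )


def make_tetraloop() -> Motif:
    """GNRA-type tetraloop on a 2-bp stem (synthetic idealized geometry)."""
    return hairpin_motif("GAAA", "GC", bulge_dir=(1.0, 0.0, 0.8),
                         spacing=6.0, tag="tetraloop-GAAA")


def make_sarcin_like_loop() -> Motif:
    """Sarcin-ricin-like 5-nt loop on a 2-bp stem (synthetic idealized)."""
    return hairpin_motif("GUAGA", "CG", bulge_dir=(0.8, 0.8, 0.5),
                         spacing=6.2, tag="sarcin-ricin-like")


def make_internal_loop() -> Motif:
    """Symmetric 2x2 internal loop flanked by Watson-Crick pairs at both ends.

    Built as two strands bridging two 1-bp flanks separated by three helical
    steps, with the unpaired nucleotides bulged radially outward (synthetic
    idealized geometry).
    """
    rise, twist = FIBER_PARAMS["A-RNA"]
    rows: list = []
    p_points: list = []
    gap = 3  # helical steps between the flanking pairs
    # strand 1 (chain S): flank1 res1, bulged res2-3, flank2 res4
    _place_residue(rows, p_points, "G", _rz(0.0), np.zeros(3), "S", 1, False)
    q0 = _rz(twist) @ _P_LOCAL + np.array([0.0, 0.0, rise])
    qe = _rz(gap * twist) @ _P_LOCAL + np.array([0.0, 0.0, gap * rise])
    arc = _arc_points(q0, qe, np.array([1.0, 0.2, 0.0]), 2, spacing=6.0)
    frames = _loop_frames(arc, qe)
    for k in range(2):
        t = arc[k] - frames[k] @ _P_LOCAL
        _place_residue(rows, p_points, "AU"[k], frames[k], t, "S", 2 + k, True)
    _place_residue(rows, p_points, "C", _rz(gap * twist),
                   np.array([0.0, 0.0, gap * rise]), "S", 4, True)
    # strand 2 (chain T), antiparallel: flank2' res1, bulged res2-3, flank1' res4
    R_t1 = _rz(gap * twist) @ _PAIR_FLIP
    _place_residue(rows, p_points, "G", R_t1, np.array([0.0, 0.0, gap * rise]),
                   "T", 1, False)
    q0t = _rz((gap - 1) * twist) @ _PAIR_FLIP @ _P_LOCAL + np.array(
        [0.0, 0.0, (gap - 1) * rise])
    qet = _PAIR_FLIP @ _P_LOCAL
    arc_t = _arc_points(q0t, qet, np.array([-1.0, -0.2, 0.0]), 2, spacing=6.0)
    frames_t = _loop_frames(arc_t, qet)
    for k in range(2):
        t = arc_t[k] - frames_t[k] @ _P_LOCAL
        _place_residue(rows, p_points, "GA"[k], frames_t[k], t, "T", 2 + k, True)
    _place_residue(rows, p_points, "C", _PAIR_FLIP, np.zeros(3), "T", 4, True)
    pairs = [(("S", 1), ("T", 4)), (("S", 4), ("T", 1))]
    annotations = [{"res_i": a, "res_j": b, "type": "WC"} for a, b in pairs]
    return Motif(
        fragment=AtomicModel.from_rows(rows),
        p_pattern=np.array(p_points),
        flanking_pairs=pairs,
        pair_annotations=annotations,
        tag="internal-loop-2x2",
    )


def default_library() -> list[Motif]:
    """The three bundled synthetic loop motifs."""
    return [make_tetraloop(), make_sarcin_like_loop(), make_internal_loop()]


# ---------------------------------------------------------------------------
# Library persistence: PDB fragment + JSON sidecar per motif
# ---------------------------------------------------------------------------

def save_library(motifs: list[Motif], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, motif in enumerate(motifs):
        stem = f"motif_{i:02d}_{motif.tag or 'fragment'}".replace(" ", "_")
        motif.fragment.write_pdb(str(directory / f"{stem}.pdb"))
        meta = {
            "tag": motif.tag,
            "flanking_pairs": [[list(a), list(b)] for a, b in motif.flanking_pairs],
            "pair_annotations": [
                {"res_i": list(ann["res_i"]), "res_j": list(ann["res_j"]),
                 "type": ann["type"]}
                for ann in motif.pair_annotations
            ],
        }
        (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))


def load_library(directory: str | Path) -> list[Motif]:
    directory = Path(directory)
    motifs = []
    for pdb_path in sorted(directory.glob("*.pdb")):
        fragment = AtomicModel.read_pdb(str(pdb_path))
        meta_path = pdb_path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        p_pattern = fragment.atoms_named("P")
        motifs.append(Motif(
            fragment=fragment,
            p_pattern=p_pattern,
            flanking_pairs=[(tuple([a[0], int(a[1])]), tuple([b[0], int(b[1])]))
                            for a, b in meta.get("flanking_pairs", [])],
            pair_annotations=[
                {"res_i": (ann["res_i"][0], int(ann["res_i"][1])),
                 "res_j": (ann["res_j"][0], int(ann["res_j"][1])),
                 "type": ann["type"]}
                for ann in meta.get("pair_annotations", [])
            ],
            tag=meta.get("tag", pdb_path.stem),
        ))
    return motifs
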