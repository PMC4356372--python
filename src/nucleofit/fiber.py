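"""Idealized fiber-model generator for A-RNA and B-DNA duplexes.

Nucleotides are assembled from standard planar base geometries expressed in
the base-pair reference frame (origin between the paired bases, x toward the
major groove, z along the helix axis) plus a sugar-phosphate backbone whose
coordinates were solved numerically so that the phosphodiester chain closes
exactly (O3'(i-1)-P(i) = 1.59 Å) under the helical screw of each form:

* A-form: rise 2.81 Å, twist 32.7 deg (phosphate radius 9.2 Å, P-P 5.9 Å)
* B-form: rise 3.38 Å, twist 36.0 deg (phosphate radius 9.2 Å, P-P 6.6 Å)

The geometry is idealized (synthetic): bases are exactly coplanar within a
pair, the helix axis is straight, and sugar puckers are stylized.  Every
duplex produced here has exact helical symmetry, which the rest of the
package exploits both as a motif source and as planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal_maps import AtomicModel

__all__ = [
    "HelixSpec",
    "Motif",
    "generate_helix",
    "complement",
    "FIBER_PARAMS",
    "BASE_FRAME",
    "WC_HBONDS",
    "nucleotide_template",
]

#: (rise Å, twist deg) canonical fiber-diffraction constants
FIBER_PARAMS = {"A-RNA": (2.81, 32.7), "B-DNA": (3.38, 36.0)}

# planar base atoms in the standard base reference frame (Å); C1' included.
# Idealized values; z = 0 for all ring atoms.
BASE_FRAME: dict[str, list[tuple[str, float, float, float]]] = {
    "A": [
        ("C1'", -2.479, 5.346, 0.0), ("N9", -1.291, 4.498, 0.0),
        ("C8", 0.024, 4.897, 0.0), ("N7", 0.877, 3.902, 0.0),
        ("C5", 0.071, 2.771, 0.0), ("C6", 0.369, 1.398, 0.0),
        ("N6", 1.611, 0.909, 0.0), ("N1", -0.668, 0.532, 0.0),
        ("C2", -1.912, 1.023, 0.0), ("N3", -2.320, 2.290, 0.0),
        ("C4", -1.267, 3.124, 0.0),
    ],
    "G": [
        ("C1'", -2.477, 5.399, 0.0), ("N9", -1.289, 4.551, 0.0),
        ("C8", 0.023, 4.962, 0.0), ("N7", 0.870, 3.969, 0.0),
        ("C5", 0.071, 2.833, 0.0), ("C6", 0.424, 1.460, 0.0),
        ("O6", 1.554, 0.955, 0.0), ("N1", -0.700, 0.641, 0.0),
        ("C2", -1.999, 1.087, 0.0), ("N2", -2.949, 0.139, 0.0),
        ("N3", -2.342, 2.364, 0.0), ("C4", -1.265, 3.177, 0.0),
    ],
    "C": [
        ("C1'", -2.477, 5.402, 0.0), ("N1", -1.285, 4.542, 0.0),
        ("C2", -1.472, 3.158, 0.0), ("O2", -2.628, 2.709, 0.0),
        ("N3", -0.391, 2.344, 0.0), ("C4", 0.837, 2.868, 0.0),
        ("N4", 1.875, 2.027, 0.0), ("C5", 1.056, 4.275, 0.0),
        ("C6", -0.023, 5.068, 0.0),
    ],
    "U": [
        ("C1'", -2.481, 5.354, 0.0), ("N1", -1.284, 4.500, 0.0),
        ("C2", -1.462, 3.131, 0.0), ("O2", -2.563, 2.608, 0.0),
        ("N3", -0.302, 2.397, 0.0), ("C4", 0.989, 2.884, 0.0),
        ("O4", 1.935, 2.094, 0.0), ("C5", 1.089, 4.311, 0.0),
        ("C6", -0.024, 5.053, 0.0),
    ],
    "T": [
        ("C1'", -2.481, 5.354, 0.0), ("N1", -1.284, 4.500, 0.0),
        ("C2", -1.462, 3.135, 0.0), ("O2", -2.562, 2.608, 0.0),
        ("N3", -0.298, 2.407, 0.0), ("C4", 0.994, 2.897, 0.0),
        ("O4", 1.944, 2.119, 0.0), ("C5", 1.106, 4.338, 0.0),
        ("C7", 2.466, 4.961, 0.0), ("C6", -0.024, 5.057, 0.0),
    ],
}

# sugar-phosphate backbone in the base frame, solved per form so the chain
# closes under the helical screw (see module docstring); C1' comes from
# BASE_FRAME.  OP1/OP2 are placed off the P.
BACKBONE: dict[str, list[tuple[str, float, float, float]]] = {
    "A-RNA": [
        ("O4'", -3.253, 6.342, 0.658), ("C4'", -4.680, 6.241, 0.387),
        ("C5'", -5.104, 7.207, -0.693), ("O5'", -4.471, 6.949, -1.949),
        ("P", -3.916, 8.325, -2.521),
        ("C2'", -3.508, 4.529, -0.771), ("C3'", -4.862, 4.831, -0.149),
        ("O3'", -6.254, 4.601, 0.009), ("O2'", -3.008, 4.329, -2.071),
    ],
    "B-DNA": [
        ("O4'", -3.113, 6.605, 0.189), ("C4'", -4.553, 6.569, -0.024),
        ("C5'", -4.936, 7.249, -1.316), ("O5'", -3.914, 7.165, -2.313),
        ("P", -3.258, 8.604, -2.479),
        ("C2'", -3.622, 4.410, -0.372), ("C3'", -4.908, 5.093, 0.065),
        ("O3'", -6.232, 4.692, 0.383),
    ],
}


def _phosphate_oxygens(form: str) -> list[tuple[str, float, float, float]]:
    """OP1/OP2 placed tetrahedrally off P, clear of the O5'-P-O3' bridge."""
    coords = {n: np.array([x, y, z]) for n, x, y, z in BACKBONE[form]}
    rise, twist = FIBER_PARAMS[form]
    p, o5 = coords["P"], coords["O5'"]
    # previous residue's O3' expressed in this base frame
    prev_o3 = _rz(-twist) @ coords["O3'"] + np.array([0.0, 0.0, -rise])
    u1 = (o5 - p) / np.linalg.norm(o5 - p)
    u2 = (prev_o3 - p) / np.linalg.norm(prev_o3 - p)
    bisector = -(u1 + u2)
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(u1, u2)
    normal /= np.linalg.norm(normal)
    half = np.radians(60.0)
    out = []
    for name, sign in (("OP1", 1.0), ("OP2", -1.0)):
        pos = p + 1.48 * (np.cos(half) * bisector + sign * np.sin(half) * normal)
        out.append((name, float(pos[0]), float(pos[1]), float(pos[2])))
    return out

#: Watson-Crick hydrogen-bond donor/acceptor atom pairs, (purine, pyrimidine)
WC_HBONDS = {
    ("G", "C"): [("N1", "N3"), ("O6", "N4"), ("N2", "O2")],
    ("A", "U"): [("N1", "N3"), ("N6", "O4")],
    ("A", "T"): [("N1", "N3"), ("N6", "O4")],
}

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def complement(base: str, form: str) -> str:
    table = _RNA_COMPLEMENT if form == "A-RNA" else _DNA_COMPLEMENT
    return table[base]


def _resname(base: str, form: str) -> str:
    return base if form == "A-RNA" else "D" + base


def nucleotide_template(base: str, form: str, with_phosphate: bool = True
                        ) -> list[tuple[str, np.ndarray]]:
    """(atom name, base-frame position) list for one nucleotide."""
    atoms = [(n, np.array([x, y, z])) for n, x, y, z in BASE_FRAME[base]]
    for n, x, y, z in BACKBONE[form]:
        if not with_phosphate and n in ("P", "OP1", "OP2"):
            continue
        atoms.append((n, np.array([x, y, z])))
    return atoms


def _rz(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

# flips a base frame into its paired mate (180 deg about the frame x axis)
_PAIR_FLIP = np.diag([1.0, -1.0, -1.0])

for _form in list(BACKBONE):
    BACKBONE[_form] = BACKBONE[_form] + _phosphate_oxygens(_form)


@dataclass
class HelixSpec:
    """Specification of an idealized double helix."""

    form: str                      # "A-RNA" | "B-DNA"
    n_pairs: int
    sequence: str | None = None    # strand-1 sequence, 5'->3'

    def __post_init__(self) -> None:
        if self.form not in FIBER_PARAMS:
            raise ValueError(f"unknown helix form: {self.form}")
        if self.n_pairs < 3:
            raise ValueError("a helix needs at least 3 base pairs")
        alphabet = "ACGU" if self.form == "A-RNA" else "ACGT"
        if self.sequence is None:
            self.sequence = ("GC" * self.n_pairs)[: self.n_pairs]
        if len(self.sequence) != self.n_pairs:
            raise ValueError("sequence length must equal n_pairs")
        if any(b not in alphabet for b in self.sequence):
            raise ValueError(f"sequence must use alphabet {alphabet}")


@dataclass
class Motif:
    """A rigid nucleic-acid fragment with its phosphate pattern and pairing.

    ``flanking_pairs`` are (residue key, residue key) tuples naming the
    Watson-Crick pairs through which the motif can be attached to a stem;
    residue keys are (chain id, residue number).  ``pair_annotations`` lists
    every base pair in the fragment with a WC/noncanonical label.
    """

    fragment: AtomicModel
    p_pattern: np.ndarray
    flanking_pairs: list = field(default_factory=list)
    pair_annotations: list = field(default_factory=list)
    tag: str = ""

    def __post_init__(self) -> None:
        self.p_pattern = np.asarray(self.p_pattern, float).reshape(-1, 3)

    @property
    def n_phosphates(self) -> int:
        return len(self.p_pattern)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Motif":
        return Motif(
            fragment=self.fragment.transformed(R, t),
            p_pattern=self.p_pattern @ np.asarray(R, float).T + np.asarray(t, float),
            flanking_pairs=list(self.flanking_pairs),
            pair_annotations=list(self.pair_annotations),
            tag=self.tag,
        )

    def residue_atoms(self, key: tuple[str, int]) -> np.ndarray:
        ch, rs = key
        return np.where((self.fragment.chain == ch) & (self.fragment.resseq == rs))[0]


def generate_helix(spec: HelixSpec) -> Motif:
    """Build an idealized duplex with exact helical symmetry.

    Strand 1 occupies chain A (residues 1..n, 5'->3'), strand 2 chain B
    (residues 1..n, 5'->3'); chain B residue j pairs chain A residue
    n + 1 - j.  The 5'-terminal residue of each strand carries no
    phosphate group.  The phosphate pattern lists chain A P atoms first.
    """
    rise, twist = FIBER_PARAMS[spec.form]
    n = spec.n_pairs
    rows = []
    p_points = []

    def place(letter: str, frame_R: np.ndarray, frame_t: np.ndarray,
              chain: str, resseq: int, with_p: bool) -> None:
        resname = _resname(letter, spec.form)
        for name, local in nucleotide_template(letter, spec.form, with_p):
            pos = frame_R @ local + frame_t
            elem = name[0] if name[0] != "O" else "O"
            rows.append((elem, name, resname, resseq, chain,
                         tuple(pos), 20.0, 1.0))
            if name == "P":
                p_points.append(pos)

    # strand 1 (chain A)
    for i in range(n):
        R = _rz(i * twist)
        t = np.array([0.0, 0.0, i * rise])
        place(spec.sequence[i], R, t, "A", i + 1, with_p=i > 0)
    # strand 2 (chain B), antiparallel: residue j pairs chain A residue n-j+1
    for j in range(n):
        i = n - 1 - j  # paired strand-1 index
        R = _rz(i * twist) @ _PAIR_FLIP
        t = np.array([0.0, 0.0, i * rise])
        place(complement(spec.sequence[i], spec.form), R, t, "B", j + 1,
              with_p=j > 0)

    fragment = AtomicModel.from_rows(rows)
    pairs = [(("A", i + 1), ("B", n - i)) for i in range(n)]
    annotations = [
        {"res_i": a, "res_j": b, "type": "WC"} for a, b in pairs
    ]
    return Motif(
        fragment=fragment,
        p_pattern=np.array(p_points),
        flanking_pairs=[pairs[0], pairs[-1]],
        pair_annotations=annotations,
        tag=f"{spec.form}-{n}bp",
    )
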