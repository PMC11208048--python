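"""Write predicted CA positions into a model and restore loop geometry.

``apply_predicted_calphas`` moves each H3 residue rigidly by its CA
displacement (a chemically reasonable initialisation). ``idealize_loop``
then minimises a geometric objective — harmonic restraints to ideal bond
lengths, cosine-harmonic bond angles, omega planarity and a soft nonbonded
repulsion — over the loop's non-CA atoms, with CA atoms either hard-fixed
(first pass) or harmonically restrained (second pass, default force
constant 10 kcal/mol/A^2). Ideal values are Engh/Huber-style constants;
gradients come from the package autodiff and the line search is the
monotone L-BFGS-B of scipy, so the objective never increases end-to-end.

An external minimiser can replace the built-in idealizer through a simple
subprocess contract (PDB text in, PDB text out).
"""

from __future__ import annotations

import json
import subprocess
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .autodiff import Tensor
from .structures import AntibodyStructure, H3Annotation, StructureError, parse_structure, write_structure

# Engh/Huber-style ideal internal coordinates
IDEAL_BONDS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.521,
    ("C", "N+"): 1.329,  # peptide bond to the next residue
}
IDEAL_ANGLES_DEG = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N+"): 116.2,
    ("C", "N+", "CA+"): 121.7,
    ("N", "CA", "CB"): 110.4,
}
CLASH_MIN_DIST = 2.8  # heavy-atom soft-sphere radius sum, A
K_BOND = 100.0
K_ANGLE = 50.0
K_OMEGA = 20.0
K_CLASH = 50.0


@dataclass(frozen=True)
class RestraintSpec:
    """CA restraint for loop idealization.

    ``force_constant`` is the harmonic constant (kcal/mol/A^2) applied to
    loop CA atoms in the release passes; ``inf`` keeps CA hard-fixed
    throughout, 0 relaxes the loop completely.
    """

    force_constant: float = 10.0
    max_cycles: int = 400
    tol: float = 1e-12
    # below this pure-geometry objective the loop counts as already ideal
    # (max bond deviation ~0.02 A / no clashes) and is returned unchanged
    already_ideal_objective: float = 0.05

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")


@dataclass
class GeometryReport:
    max_bond_dev_before: float
    max_bond_dev_after: float
    clash_count_before: int
    clash_count_after: int
    objective_before: float
    objective_after: float
    converged: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "max_bond_dev_A": self.max_bond_dev_after,
                "max_bond_dev_before_A": self.max_bond_dev_before,
                "clash_count_before": self.clash_count_before,
                "clash_count_after": self.clash_count_after,
                "objective_before": self.objective_before,
                "objective_after": self.objective_after,
                "converged": self.converged,
            }
        )


def apply_predicted_calphas(
    model: AntibodyStructure, ann: H3Annotation, coords: np.ndarray
) -> AntibodyStructure:
    """Set H3 CA positions to ``coords``; co-translate each residue rigidly."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (ann.length, 3):
        raise StructureError(
            f"expected coords of shape ({ann.length}, 3), got {coords.shape}"
        )
    out = model.copy()
    chain = out.chain(ann.chain_id)
    for k, i in enumerate(ann.indices):
        res = chain[i]
        shift = coords[k] - res.coord("CA")
        for atom in res.atoms:
            atom.coord = atom.coord + shift
    return out


# ---------------------------------------------------------------------------
# geometric idealizer


class _LoopSystem:
    """Flattened atom table + term index lists for one H3 loop."""

    def __init__(self, model: AntibodyStructure, ann: H3Annotation):
        chain = model.chain(ann.chain_id)
        self.atom_keys: list[tuple[int, int]] = []  # (residue seq_index, atom pos)
        index = {}
        lo = max(0, ann.start_index - 1)
        hi = min(len(chain) - 1, ann.end_index + 1)
        for i in range(lo, hi + 1):
            for j, a in enumerate(chain[i].atoms):
                index[(i, a.name)] = len(self.atom_keys)
                self.atom_keys.append((i, j))
        self.coords0 = np.array(
            [chain[i].atoms[j].coord for i, j in self.atom_keys]
        )
        self.in_loop = np.array(
            [ann.start_index <= i <= ann.end_index for i, _ in self.atom_keys]
        )
        self.is_ca = np.array(
            [chain[i].atoms[j].name == "CA" for i, j in self.atom_keys]
        )

        def at(i, name):
            return index.get((i, name))

        self.bonds: list[tuple[int, int, float]] = []
        self.angles: list[tuple[int, int, int, float]] = []
        self.omegas: list[tuple[int, int, int, int]] = []
        bonded_pairs = set()
        for i in range(lo, hi + 1):
            for (a, b), d0 in IDEAL_BONDS.items():
                ia = at(i, a)
                ib = at(i + 1, "N") if b == "N+" else at(i, b)
                if ia is not None and ib is not None:
                    self.bonds.append((ia, ib, d0))
                    bonded_pairs.add(frozenset((ia, ib)))
            for (a, b, c), theta in IDEAL_ANGLES_DEG.items():
                ia = at(i, a)
                ib = at(i + 1, "N") if b == "N+" else at(i, b)
                ic = at(i + 1, "CA") if c == "CA+" else (
                    at(i + 1, "N") if c == "N+" else at(i, c))
                if None not in (ia, ib, ic):
                    self.angles.append((ia, ib, ic, np.deg2rad(theta)))
                    bonded_pairs.add(frozenset((ia, ic)))
            quad = (at(i, "CA"), at(i, "C"), at(i + 1, "N"), at(i + 1, "CA"))
            if None not in quad:
                self.omegas.append(quad)

        # nonbonded pairs: heavy atoms >= 2 residues apart or same-residue
        # non-bonded, at least one side in the loop
        n = len(self.atom_keys)
        self.nb_pairs = []
        res_of = np.array([i for i, _ in self.atom_keys])
        for a in range(n):
            for b in range(a + 1, n):
                if not (self.in_loop[a] or self.in_loop[b]):
                    continue
                if abs(res_of[a] - res_of[b]) <= 1:
                    continue
                if frozenset((a, b)) in bonded_pairs:
                    continue
                self.nb_pairs.append((a, b))

    def objective(
        self,
        x: Tensor,
        ca_anchor: np.ndarray | None,
        k_ca: float,
        tether: tuple[np.ndarray, float] | None = None,
    ) -> Tensor:
        eps = 1e-12
        total = Tensor(0.0)
        if self.bonds:
            ia, ib, d0 = (np.array(v) for v in zip(*self.bonds))
            d = (((x[ia] - x[ib]) ** 2).sum(axis=-1) + eps).sqrt()
            total = total + K_BOND * ((d - d0) ** 2).sum()
        if self.angles:
            ia, ib, ic, th0 = (np.array(v) for v in zip(*self.angles))
            u = x[ia] - x[ib]
            v = x[ic] - x[ib]
            cos = (u * v).sum(axis=-1) / (
                (((u**2).sum(axis=-1) + eps) * ((v**2).sum(axis=-1) + eps)).sqrt()
            )
            total = total + K_ANGLE * ((cos - np.cos(th0)) ** 2).sum()
        for ia, ib, ic, idd in self.omegas:
            b0 = x[ib] - x[ia]
            b1 = x[ic] - x[ib]
            b2 = x[idd] - x[ic]
            n1x = _cross(b0, b1)
            n2x = _cross(b1, b2)
            cosw = (n1x * n2x).sum() / (
                (((n1x**2).sum() + eps) * ((n2x**2).sum() + eps)).sqrt()
            )
            total = total + K_OMEGA * (cosw + 1.0) ** 2
        if self.nb_pairs:
            ia, ib = (np.array(v) for v in zip(*self.nb_pairs))
            d = (((x[ia] - x[ib]) ** 2).sum(axis=-1) + eps).sqrt()
            overlap = (CLASH_MIN_DIST - d).relu()
            total = total + K_CLASH * (overlap**2).sum()
        if ca_anchor is not None and k_ca > 0:
            ca_idx = np.flatnonzero(self.is_ca & self.in_loop)
            dev = x[ca_idx] - ca_anchor
            total = total + k_ca * (dev**2).sum()
        if tether is not None:
            idx, ref, k_t = tether
            total = total + k_t * ((x[idx] - ref) ** 2).sum()
        return total

    def bond_devs(self, coords: np.ndarray) -> np.ndarray:
        if not self.bonds:
            return np.zeros(0)
        ia, ib, d0 = (np.array(v) for v in zip(*self.bonds))
        d = np.linalg.norm(coords[ia] - coords[ib], axis=-1)
        return np.abs(d - d0)

    def clash_count(self, coords: np.ndarray) -> int:
        if not self.nb_pairs:
            return 0
        ia, ib = (np.array(v) for v in zip(*self.nb_pairs))
        d = np.linalg.norm(coords[ia] - coords[ib], axis=-1)
        return int(np.sum(d < CLASH_MIN_DIST))


def _cross(a: Tensor, b: Tensor) -> Tensor:
    from .autodiff import stack

    ax, ay, az = a[0], a[1], a[2]
    bx, by, bz = b[0], b[1], b[2]
    return stack([ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx])


def idealize_loop(
    model: AntibodyStructure,
    ann: H3Annotation,
    spec: RestraintSpec = RestraintSpec(),
) -> tuple[AntibodyStructure, GeometryReport]:
    """Two-pass geometric idealization of the H3 loop around its CA trace.

    Pass 1 optimises non-CA loop atoms with CA hard-fixed; pass 2 releases
    the CA atoms under a harmonic restraint of ``spec.force_constant``
    toward their pass-1 positions. Atoms outside the span never move.
    """
    sys = _LoopSystem(model, ann)
    movable_p1 = sys.in_loop & ~sys.is_ca
    coords = sys.coords0.copy()
    obj0 = float(sys.objective(Tensor(coords), None, 0.0).data)
    report_before = (sys.bond_devs(coords).max(initial=0.0), sys.clash_count(coords))

    if obj0 <= spec.already_ideal_objective:
        # geometry already ideal: exact fixed point, nothing to do
        dev = float(report_before[0])
        return model.copy(), GeometryReport(
            max_bond_dev_before=dev, max_bond_dev_after=dev,
            clash_count_before=int(report_before[1]),
            clash_count_after=int(report_before[1]),
            objective_before=obj0, objective_after=obj0, converged=True,
        )

    converged = True

    def run_pass(movable, ca_anchor, k_ca, k_tether=0.0):
        nonlocal converged
        idx = np.flatnonzero(movable)
        if idx.size == 0:
            return
        tether = (idx, coords[idx].copy(), k_tether) if k_tether > 0 else None

        def fun(flat):
            full = coords.copy()
            full[idx] = flat.reshape(-1, 3)
            x = Tensor(full)
            x.requires_grad = True  # grads for all rows; only movable used
            obj = sys.objective(x, ca_anchor, k_ca, tether)
            obj.backward()
            return float(obj.data), x.grad[idx].ravel()

        res = minimize(
            fun,
            coords[idx].ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": spec.max_cycles, "ftol": spec.tol, "gtol": 1e-8},
        )
        coords[idx] = res.x.reshape(-1, 3)
        converged = converged and bool(res.success or res.status == 1)

    # Every pass carries a weak all-atom tether to its own starting point.
    # The bonded terms are ~3 orders stiffer, so the tether does not disturb
    # ideal geometry; it regularises the loop's near-zero-stiffness modes so
    # each pass has a unique endpoint and re-running the idealizer on its
    # own output stays put (idempotence).
    k_tether = 0.05

    # pass 1: non-CA atoms with the CA trace hard-fixed
    run_pass(movable_p1, None, 0.0, k_tether=k_tether)
    if np.isfinite(spec.force_constant):
        # release: damped cycles under a harmonic CA restraint (anchor at
        # the current trace), then tethered free passes iterated to a
        # movement tolerance ("complete relaxation" of the whole loop)
        loop_ca = sys.is_ca & sys.in_loop
        if spec.force_constant > 0:
            for _ in range(2):
                anchor = coords[loop_ca].copy()
                run_pass(sys.in_loop, anchor, spec.force_constant,
                         k_tether=k_tether)
        for _ in range(6):
            start = coords[sys.in_loop].copy()
            run_pass(sys.in_loop, None, 0.0, k_tether=k_tether)
            obj_now = float(sys.objective(Tensor(coords), None, 0.0).data)
            if (np.abs(coords[sys.in_loop] - start).max() < 1e-4
                    or obj_now <= 0.2 * spec.already_ideal_objective):
                break
        else:
            converged = converged and float(
                sys.objective(Tensor(coords), None, 0.0).data
            ) <= spec.already_ideal_objective

    obj1 = float(sys.objective(Tensor(coords), None, 0.0).data)
    if obj1 > obj0:  # line searches are monotone; keep the better point
        coords = sys.coords0.copy()
        obj1 = obj0
        converged = False

    out = model.copy()
    chain = out.chain(ann.chain_id)
    for (i, j), xyz in zip(sys.atom_keys, coords):
        if ann.start_index <= i <= ann.end_index:
            chain[i].atoms[j].coord = xyz.copy()
    report = GeometryReport(
        max_bond_dev_before=float(report_before[0]),
        max_bond_dev_after=float(sys.bond_devs(coords).max(initial=0.0)),
        clash_count_before=int(report_before[1]),
        clash_count_after=sys.clash_count(coords),
        objective_before=obj0,
        objective_after=obj1,
        converged=converged,
    )
    return out, report


def idealize_external(
    model: AntibodyStructure, command: list[str], timeout: float = 600.0
) -> AntibodyStructure:
    """Hook for an external minimiser: PDB text on stdin, PDB text on stdout."""
    proc = subprocess.run(
        command,
        input=write_structure(model),
        capture_output=True,
        text=True,
        timeout=timeout,
        check=True,
    )
    return parse_structure(proc.stdout, source="external minimiser")
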