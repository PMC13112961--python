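"""Two-link planar arm: kinematics, inverse dynamics, and a forward-simulation oracle.

The arm is modelled in the horizontal plane (no gravity) with the shoulder at the
origin.  Angle conventions:

* ``theta_s`` — shoulder angle, measured from the +x axis.
* ``theta_e`` — elbow angle in ``[-pi, 0]``; ``-pi`` is full extension
  (collinear limbs), ``0`` fully folded.

Under this convention the hand position is::

    x = l1*cos(theta_s) - l2*cos(theta_s + theta_e)
    y = l1*sin(theta_s) - l2*sin(theta_s + theta_e)

whose analytic inverse is the two-``arccos`` form used throughout the package.
Joint torques follow the rigid-body equation of motion ``T = M(q) qdd + V(q, qd)``
with the manipulandum (handle) treated as a planar point-mass pair acting at the
hand, mapped through the transpose Jacobian: ``M = MA + J^T Mm J``.  All units SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ArmParameters",
    "ManipulandumParameters",
    "JointState",
    "TorqueSample",
    "ReachabilityError",
    "forward_kinematics",
    "inverse_kinematics",
    "jacobian",
    "mass_matrix",
    "coriolis_vector",
    "inverse_dynamics",
    "forward_simulate",
]


class ReachabilityError(ValueError):
    """Hand position outside the annulus reachable by the two links."""


@dataclass(frozen=True)
class ArmParameters:
    """Physical constants of the two-link arm.

    Inertias default to uniform-rod values about the proximal joint
    (``I = m l^2 / 3``); the centre of gravity of the forearm defaults to its
    midpoint.  Lengths in metres, masses in kilograms, inertias in kg m^2.
    """

    l1: float = 0.132
    l2: float = 0.207
    m1: float = 0.295
    m2: float = 0.280
    lg2: Optional[float] = None
    I1: Optional[float] = None
    I2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lg2 is None:
            object.__setattr__(self, "lg2", self.l2 / 2.0)
        if self.I1 is None:
            object.__setattr__(self, "I1", self.m1 * self.l1 ** 2 / 3.0)
        if self.I2 is None:
            object.__setattr__(self, "I2", self.m2 * self.l2 ** 2 / 3.0)
        for name in ("l1", "l2", "m1", "m2", "lg2", "I1", "I2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ArmParameters.{name} must be strictly positive")
        if self.lg2 > self.l2:
            raise ValueError("lg2 must not exceed the forearm length l2")

    @property
    def reach_min(self) -> float:
        return abs(self.l1 - self.l2)

    @property
    def reach_max(self) -> float:
        return self.l1 + self.l2


@dataclass(frozen=True)
class ManipulandumParameters:
    """Planar point-mass model of the handle the subject pushes.

    ``masses`` are the effective masses along x and y (kg).  With
    ``enabled=False`` (or zero masses) the coupling term vanishes and the arm
    equation of motion reduces to ``TA = MA qdd + VA``.
    """

    masses: tuple[float, float] = (0.565, 0.065)
    enabled: bool = True

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.masses):
            raise ValueError("manipulandum masses must be non-negative")

    @property
    def mass_matrix(self) -> np.ndarray:
        if not self.enabled:
            return np.zeros((2, 2))
        return np.diag(np.asarray(self.masses, dtype=float))


@dataclass
class JointState:
    """Joint angles and optional time derivatives, scalar or series.

    All fields broadcast against each other; a single sample and a series of
    one are treated identically.
    """

    theta_s: np.ndarray
    theta_e: np.ndarray
    omega_s: Optional[np.ndarray] = None
    omega_e: Optional[np.ndarray] = None
    alpha_s: Optional[np.ndarray] = None
    alpha_e: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.theta_s = np.asarray(self.theta_s, dtype=float)
        self.theta_e = np.asarray(self.theta_e, dtype=float)
        for name in ("omega_s", "omega_e", "alpha_s", "alpha_e"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def require(self, *fields: str) -> None:
        for f in fields:
            if getattr(self, f) is None:
                raise ValueError(f"JointState.{f} is required for this operation")


@dataclass
class TorqueSample:
    """Shoulder and elbow torques (N m), scalar or series."""

    tau_s: np.ndarray
    tau_e: np.ndarray

    def __post_init__(self) -> None:
        self.tau_s = np.asarray(self.tau_s, dtype=float)
        self.tau_e = np.asarray(self.tau_e, dtype=float)

    def as_array(self) -> np.ndarray:
        """Stack to shape ``(..., 2)``."""
        return np.stack(np.broadcast_arrays(self.tau_s, self.tau_e), axis=-1)


def forward_kinematics(state: JointState, arm: ArmParameters = ArmParameters()):
    """Hand position (x, y) in metres for the given joint angles."""
    ts, te = state.theta_s, state.theta_e
    x = arm.l1 * np.cos(ts) - arm.l2 * np.cos(ts + te)
    y = arm.l1 * np.sin(ts) - arm.l2 * np.sin(ts + te)
    return x, y


def inverse_kinematics(x, y, arm: ArmParameters = ArmParameters(), atol: float = 1e-9):
    """Joint angles for a planar hand position.

    Returns ``(theta_s, theta_e)`` with ``theta_e`` on the canonical branch
    ``[-pi, 0]``.  Raises :class:`ReachabilityError` if any sample lies outside
    the reachable annulus (beyond a small tolerance ``atol`` used to absorb
    round-off at the boundary).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    r = np.sqrt(r2)
    if np.any(r > arm.reach_max + atol) or np.any(r < arm.reach_min - atol):
        bad = np.flatnonzero((r > arm.reach_max + atol) | (r < arm.reach_min - atol))
        raise ReachabilityError(
            f"{bad.size} hand sample(s) outside reachable annulus "
            f"[{arm.reach_min:.4f}, {arm.reach_max:.4f}] m; first offending index {bad[0]}"
        )
    ce = (arm.l1 ** 2 + arm.l2 ** 2 - r2) / (2.0 * arm.l1 * arm.l2)
    cs = (arm.l1 ** 2 - arm.l2 ** 2 + r2) / (2.0 * arm.l1 * r)
    theta_e = -np.arccos(np.clip(ce, -1.0, 1.0))
    theta_s = np.arctan2(y, x) - np.arccos(np.clip(cs, -1.0, 1.0))
    # principal branch (-pi, pi]; the two-arccos form can underflow by 2*pi
    theta_s = -(np.mod(-theta_s + np.pi, 2.0 * np.pi) - np.pi)
    return theta_s, theta_e


def jacobian(state: JointState, arm: ArmParameters = ArmParameters()) -> np.ndarray:
    """Hand-velocity Jacobian, shape ``(..., 2, 2)``: ``v_hand = J @ [ws, we]``."""
    ts, te = np.broadcast_arrays(state.theta_s, state.theta_e)
    s1, c1 = np.sin(ts), np.cos(ts)
    s12, c12 = np.sin(ts + te), np.cos(ts + te)
    J = np.empty(ts.shape + (2, 2))
    J[..., 0, 0] = -arm.l1 * s1 + arm.l2 * s12
    J[..., 0, 1] = arm.l2 * s12
    J[..., 1, 0] = arm.l1 * c1 - arm.l2 * c12
    J[..., 1, 1] = -arm.l2 * c12
    return J


def mass_matrix(state: JointState, arm: ArmParameters = ArmParameters()) -> np.ndarray:
    """Arm inertia matrix ``MA(theta_e)``, shape ``(..., 2, 2)``, symmetric."""
    te = np.asarray(state.theta_e, dtype=float)
    a = arm.m2 * arm.l1 * arm.lg2 * np.cos(te)
    M = np.empty(te.shape + (2, 2))
    M[..., 0, 0] = arm.I1 + arm.I2 + 2.0 * a + arm.m2 * arm.l1 ** 2
    M[..., 0, 1] = arm.I2 + a
    M[..., 1, 0] = arm.I2 + a
    M[..., 1, 1] = arm.I2
    return M


def coriolis_vector(state: JointState, arm: ArmParameters = ArmParameters()) -> np.ndarray:
    """Coriolis/centrifugal torque vector ``VA``, shape ``(..., 2)``.

    Standard two-link form, uniquely determined by the Lagrangian whose inertia
    matrix is :func:`mass_matrix`.  Zero whenever both joint velocities vanish.
    """
    state.require("omega_s", "omega_e")
    te, ws, we = np.broadcast_arrays(state.theta_e, state.omega_s, state.omega_e)
    h = arm.m2 * arm.l1 * arm.lg2 * np.sin(te)
    V = np.empty(te.shape + (2,))
    V[..., 0] = -h * (2.0 * ws * we + we * we)
    V[..., 1] = h * ws * ws
    return V


def _coupled_mass_matrix(state: JointState, arm: ArmParameters,
                         manip: Optional[ManipulandumParameters]) -> np.ndarray:
    M = mass_matrix(state, arm)
    if manip is not None and manip.enabled and any(m > 0 for m in manip.masses):
        J = jacobian(state, arm)
        Mm = manip.mass_matrix
        M = M + np.swapaxes(J, -1, -2) @ Mm @ J
    return M


def inverse_dynamics(state: JointState, arm: ArmParameters = ArmParameters(),
                     manip: Optional[ManipulandumParameters] = None) -> TorqueSample:
    """Joint torques producing the given motion.

    With the manipulandum coupling disabled this is ``TA = MA qdd + VA``; with
    coupling enabled the handle point-mass contribution enters through the
    transpose Jacobian, ``Tor = (MA + J^T Mm J) qdd + VA``.
    """
    state.require("omega_s", "omega_e", "alpha_s", "alpha_e")
    arrays = np.broadcast_arrays(state.theta_s, state.theta_e, state.omega_s,
                                 state.omega_e, state.alpha_s, state.alpha_e)
    ts, te, ws, we, als, ale = arrays
    st = JointState(ts, te, ws, we, als, ale)
    M = _coupled_mass_matrix(st, arm, manip)
    V = coriolis_vector(st, arm)
    qdd = np.stack([als, ale], axis=-1)
    tau = np.einsum("...ij,...j->...i", M, qdd) + V
    return TorqueSample(tau[..., 0], tau[..., 1])


def forward_simulate(torques: TorqueSample, initial: JointState,
                     arm: ArmParameters = ArmParameters(),
                     manip: Optional[ManipulandumParameters] = None,
                     dt: float = 1e-4) -> JointState:
    """Integrate the equation of motion under a commanded torque profile.

    Test/simulation oracle: classic fixed-step RK4 on ``(q, qd)`` with
    ``qdd = M(q)^{-1} (tau(t) - V(q, qd))``; torques are interpolated linearly
    between samples.  Returns the full state series (including accelerations
    evaluated from the dynamics at each sample) aligned with the torque grid.
    Raises :class:`numpy.linalg.LinAlgError` if the inertia matrix becomes
    singular.
    """
    tau = torques.as_array().reshape(-1, 2)
    n = tau.shape[0]
    initial.require("omega_s", "omega_e")

    def accel(q: np.ndarray, qd: np.ndarray, t: np.ndarray) -> np.ndarray:
        st = JointState(q[0], q[1], qd[0], qd[1])
        M = _coupled_mass_matrix(st, arm, manip)
        V = coriolis_vector(st, arm)
        return np.linalg.solve(M, t - V)

    def tau_at(i: float) -> np.ndarray:
        if i >= n - 1:
            return tau[-1]
        lo = int(np.floor(i))
        w = i - lo
        return (1.0 - w) * tau[lo] + w * tau[lo + 1]

    q = np.array([float(initial.theta_s), float(initial.theta_e)])
    qd = np.array([float(initial.omega_s), float(initial.omega_e)])
    out_q = np.empty((n, 2))
    out_qd = np.empty((n, 2))
    out_qdd = np.empty((n, 2))
    for i in range(n):
        out_q[i], out_qd[i] = q, qd
        out_qdd[i] = accel(q, qd, tau[i])
        if i == n - 1:
            break
        t0, th, t1 = tau[i], tau_at(i + 0.5), tau[i + 1]
        k1q, k1v = qd, accel(q, qd, t0)
        k2q, k2v = qd + 0.5 * dt * k1v, accel(q + 0.5 * dt * k1q, qd + 0.5 * dt * k1v, th)
        k3q, k3v = qd + 0.5 * dt * k2v, accel(q + 0.5 * dt * k2q, qd + 0.5 * dt * k2v, th)
        k4q, k4v = qd + dt * k3v, accel(q + dt * k3q, qd + dt * k3v, t1)
        q = q + dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
        qd = qd + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return JointState(out_q[:, 0], out_q[:, 1], out_qd[:, 0], out_qd[:, 1],
                      out_qdd[:, 0], out_qdd[:, 1])
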