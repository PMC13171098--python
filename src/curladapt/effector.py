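"""Planar two-joint arm driven by six muscle-like actuators.

The arm is a horizontal-plane, gravity-free, rigid two-link chain (shoulder +
elbow) actuated by six lumped muscles: mono-articular shoulder flexors/extensors
(SF, SE), mono-articular elbow flexors/extensors (EF, EE), and a bi-articular
flexor/extensor pair (BF, BE).  Muscles follow a simplified rigid-tendon
Hill-type model: a first-order activation filter driven by the neural
stimulation command, a Gaussian force-length factor, a smooth (tanh-saturated)
force-velocity factor, constant moment arms, and muscle length affine in the
joint angles.  An optional velocity-dependent curl field applies an external
endpoint force proportional to, and rotated 90 degrees from, the endpoint
velocity.

Every function here is a smooth map of its inputs so that gradients can be
propagated through closed-loop rollouts (see :mod:`curladapt.engine`).
Functions accept an ``xp`` array-module argument so the same code runs under
plain numpy and under automatic-differentiation oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ArmConfig",
    "ArmState",
    "CurlField",
    "curl_force",
    "forward_kinematics",
    "jacobian",
    "muscle_geometry",
    "muscle_force",
    "inertia",
    "coriolis",
    "limit_torque",
    "step",
    "endpoint_force",
]

MUSCLE_NAMES = ("SF", "SE", "EF", "EE", "BF", "BE")


def _arr(x):
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class ArmConfig:
    """Geometry, inertia and muscle parameters of the planar arm.

    Defaults are human-like: 0.30 m upper arm / 0.33 m forearm, link masses
    1.8 / 1.2 kg, uniform-rod inertias about the centre of mass.  Muscles are
    at optimal length at the reference posture ``theta_ref`` (the centre-out
    start: shoulder 60 deg, elbow 90 deg).
    """

    link_lengths: tuple[float, float] = (0.30, 0.33)
    link_masses: tuple[float, float] = (1.8, 1.2)
    com: tuple[float, float] = (0.15, 0.165)
    inertias: tuple[float, float] = (0.0135, 0.010890)
    #: signed constant moment arms, metres; rows SF, SE, EF, EE, BF, BE
    moment_arms: tuple = (
        (0.040, 0.0),
        (-0.040, 0.0),
        (0.0, 0.025),
        (0.0, -0.025),
        (0.028, 0.028),
        (-0.028, -0.028),
    )
    max_iso_force: tuple = (300.0, 300.0, 200.0, 200.0, 150.0, 150.0)
    optimal_length: tuple = (0.13, 0.13, 0.11, 0.11, 0.16, 0.16)
    tau_act: float = 0.05          # activation time constant, s
    dt: float = 0.01               # integration step, s
    joint_limits: tuple = ((0.0, 2.443), (0.0, 2.793))  # rad (shoulder, elbow)
    theta_ref: tuple[float, float] = (np.pi / 3.0, np.pi / 2.0)
    fl_width: float = 0.30         # Gaussian force-length width (l/l_opt)
    fv_gain: float = 0.9           # force-velocity modulation depth
    fv_scale: float = 5.0          # force-velocity saturation rate (l_opt/s)
    joint_damping: float = 0.05    # N*m*s passive viscosity
    limit_stiffness: float = 5.0   # N*m soft joint-limit torque scale
    limit_width: float = 0.05      # rad softness of the limit boundary
    #: |joint velocity| tolerated at rest with zero stimulation (passive-force tolerance)
    rest_tolerance: float = 1e-9

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be strictly positive")
        for name in ("link_lengths", "link_masses", "max_iso_force", "optimal_length"):
            if np.any(_arr(getattr(self, name)) <= 0):
                raise ValueError(f"{name} entries must be strictly positive")
        R = _arr(self.moment_arms)
        if R.shape != (6, 2):
            raise ValueError("moment_arms must be 6x2")
        nonzero = np.abs(R) > 0
        # SF/SE/EF/EE act on one joint, BF/BE on both
        expected = [1, 1, 1, 1, 2, 2]
        if [int(n) for n in nonzero.sum(axis=1)] != expected:
            raise ValueError("moment-arm sign pattern does not realize SF,SE,EF,EE,BF,BE")

    # cached derived arrays -------------------------------------------------
    @property
    def R(self) -> np.ndarray:
        return _arr(self.moment_arms)

    @property
    def f_max(self) -> np.ndarray:
        return _arr(self.max_iso_force)

    @property
    def l_opt(self) -> np.ndarray:
        return _arr(self.optimal_length)

    def with_(self, **kw) -> "ArmConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class CurlField:
    """Velocity-dependent curl field: F = b * [[0, -1], [1, 0]] @ v.

    ``b`` is the field gain in N*s/m: 0 for the null field, +8 for the trained
    field, -8 for the opposite-sign control field.  The returned force is
    always orthogonal to the endpoint velocity.
    """

    b: float = 0.0


@dataclass
class ArmState:
    """Full kinematic + muscle state of the arm at one instant.

    Endpoint position/velocity and normalized muscle lengths/velocities are
    derived from the joint state and kept consistent by construction; use
    :meth:`from_joints` rather than filling fields by hand.
    """

    joint_angles: np.ndarray       # (2,) rad
    joint_velocities: np.ndarray   # (2,) rad/s
    activations: np.ndarray        # (6,) in [0, 1]
    muscle_lengths: np.ndarray     # (6,) normalized l / l_opt
    muscle_velocities: np.ndarray  # (6,) normalized d(l/l_opt)/dt
    endpoint_position: np.ndarray  # (2,) m
    endpoint_velocity: np.ndarray  # (2,) m/s
    muscle_forces: np.ndarray      # (6,) N

    @classmethod
    def from_joints(cls, theta, omega, activations, cfg: ArmConfig) -> "ArmState":
        theta = _arr(theta)
        omega = _arr(omega)
        act = _arr(activations)
        if np.any(act < 0) or np.any(act > 1):
            raise ValueError("activations must lie in [0, 1]")
        ln, vn = muscle_geometry(theta, omega, cfg)
        f = muscle_force(act, ln, vn, cfg)
        p = forward_kinematics(theta, cfg)
        v = jacobian(theta, cfg) @ omega
        return cls(theta, omega, act, ln, vn, p, v, f)

    def validate(self, cfg: ArmConfig) -> None:
        for name in ("joint_angles", "joint_velocities", "activations"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise FloatingPointError(f"non-finite {name} in ArmState")
        if np.any(self.activations < 0) or np.any(self.activations > 1):
            raise ValueError("activations must lie in [0, 1]")


# ---------------------------------------------------------------------------
# kinematics and muscle model
# ---------------------------------------------------------------------------

def curl_force(endpoint_velocity, b, xp=np):
    """External curl force (F_x, F_y) = b * [[0, -1], [1, 0]] @ (vx, vy).

    Orthogonal to the velocity with magnitude |b|*|v|.  ``endpoint_velocity``
    may carry leading batch dimensions; the last axis holds (vx, vy).
    """
    v = endpoint_velocity if xp is not np else _arr(endpoint_velocity)
    if xp is np and not np.all(np.isfinite(v)):
        raise ValueError("curl_force: non-finite endpoint velocity")
    if xp is np and not np.isfinite(b):
        raise ValueError("curl_force: non-finite gain b")
    vx = v[..., 0]
    vy = v[..., 1]
    return xp.stack([-b * vy, b * vx], axis=-1)


def forward_kinematics(theta, cfg: ArmConfig, xp=np):
    """Endpoint position of the two-link chain, shoulder at the origin."""
    L1, L2 = cfg.link_lengths
    t1 = theta[..., 0]
    t12 = theta[..., 0] + theta[..., 1]
    return xp.stack(
        [L1 * xp.cos(t1) + L2 * xp.cos(t12), L1 * xp.sin(t1) + L2 * xp.sin(t12)],
        axis=-1,
    )


def jacobian(theta, cfg: ArmConfig, xp=np):
    """Endpoint Jacobian dp/dtheta, shape (..., 2, 2)."""
    L1, L2 = cfg.link_lengths
    t1 = theta[..., 0]
    t12 = theta[..., 0] + theta[..., 1]
    s1, c1 = xp.sin(t1), xp.cos(t1)
    s12, c12 = xp.sin(t12), xp.cos(t12)
    row1 = xp.stack([-L1 * s1 - L2 * s12, -L2 * s12], axis=-1)
    row2 = xp.stack([L1 * c1 + L2 * c12, L2 * c12], axis=-1)
    return xp.stack([row1, row2], axis=-2)


def muscle_geometry(theta, omega, cfg: ArmConfig, xp=np):
    """Normalized muscle lengths and velocities at a joint state.

    Muscle path length is affine in the joint angles,
    l = l_opt + R (theta_ref - theta), so muscles sit at optimal length at the
    reference posture.  Returns (l/l_opt, (dl/dt)/l_opt); positive velocity
    means the muscle is lengthening.
    """
    R = cfg.R
    l_opt = cfg.l_opt
    theta_ref = _arr(cfg.theta_ref)
    ln = 1.0 + ((theta_ref - theta) @ R.T) / l_opt
    vn = -(omega @ R.T) / l_opt
    return ln, vn


def muscle_force(activations, ln, vn, cfg: ArmConfig, xp=np):
    """Rigid-tendon Hill-type muscle tension, Newtons.

    f = f_max * a * FL(ln) * FV(vn) with a Gaussian force-length factor and a
    smooth saturating force-velocity factor (force drops when shortening,
    rises when lengthening).  No passive elastic element, so zero activation
    yields exactly zero force.
    """
    fl = xp.exp(-((ln - 1.0) ** 2) / (2.0 * cfg.fl_width**2))
    fv = 1.0 + cfg.fv_gain * xp.tanh(vn / cfg.fv_scale)
    return cfg.f_max * activations * fl * fv


def inertia(theta, cfg: ArmConfig, xp=np):
    """Joint-space inertia matrix entries (M11, M12, M22) of the chain."""
    L1, _ = cfg.link_lengths
    m1, m2 = cfg.link_masses
    r1, r2 = cfg.com
    I1, I2 = cfg.inertias
    a2 = m2 * L1 * r2
    c2 = xp.cos(theta[..., 1])
    m22 = I2 + m2 * r2**2
    m11 = I1 + I2 + m1 * r1**2 + m2 * (L1**2 + r2**2) + 2.0 * a2 * c2
    m12 = m22 + a2 * c2
    return m11, m12, m22 * xp.ones_like(m11)


def coriolis(theta, omega, cfg: ArmConfig, xp=np):
    """Coriolis/centrifugal joint torques (C1, C2)."""
    L1, _ = cfg.link_lengths
    m2 = cfg.link_masses[1]
    r2 = cfg.com[1]
    a2 = m2 * L1 * r2
    s2 = xp.sin(theta[..., 1])
    o1 = omega[..., 0]
    o2 = omega[..., 1]
    c1 = -a2 * s2 * (2.0 * o1 * o2 + o2**2)
    c2 = a2 * s2 * o1**2
    return c1, c2


def _sigmoid(x, xp=np):
    return 1.0 / (1.0 + xp.exp(-x))


def limit_torque(theta, cfg: ArmConfig, xp=np):
    """Smooth restoring torque near the joint-angle limits (softplus walls)."""
    k = cfg.limit_stiffness
    w = cfg.limit_width
    lims = _arr(cfg.joint_limits)
    lo = lims[:, 0]
    hi = lims[:, 1]
    # softplus via logaddexp keeps the expression overflow-safe and smooth
    up = xp.logaddexp(0.0, (theta - hi) / w)
    dn = xp.logaddexp(0.0, (lo - theta) / w)
    return -k * w * (up - dn)


def step(state: ArmState, stimulation, fld: CurlField, cfg: ArmConfig) -> ArmState:
    """Advance the arm one time step under a stimulation command.

    Semi-implicit Euler at ``cfg.dt``: activation filter -> muscle forces ->
    joint torques through the moment arms -> rigid-body dynamics with the curl
    force mapped through the endpoint Jacobian transpose -> velocity update ->
    position update with the *new* velocity.  The map is smooth in both the
    state and the stimulation.
    """
    stim = _arr(stimulation)
    if np.any(stim < 0.0) or np.any(stim > 1.0):
        raise ValueError("stimulation must lie in [0, 1]")
    state.validate(cfg)
    theta, omega, act = state.joint_angles, state.joint_velocities, state.activations
    th1, om1, act1, f = _step_arrays(theta, omega, act, stim, fld.b, cfg)
    for name, val in (("joint_angles", th1), ("joint_velocities", om1),
                      ("activations", act1), ("muscle_forces", f)):
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"non-finite {name} after step")
    new = ArmState.from_joints(th1, om1, np.clip(act1, 0.0, 1.0), cfg)
    new.muscle_forces = f  # forces generated *during* the step
    return new


def _step_arrays(theta, omega, act, stim, b, cfg: ArmConfig, xp=np,
                 ln=None, vn=None):
    """Array core of :func:`step`; batched over leading dimensions.

    Returns (theta', omega', act', f) where f is the muscle force produced
    during the step (with the updated activation at the current geometry).
    ``ln``/``vn`` may be supplied when the caller already holds the current
    muscle geometry (the rollout loop does).  This is the exact function the
    BPTT adjoint in :mod:`curladapt.engine` differentiates.
    """
    dt = cfg.dt
    act1 = act + (dt / cfg.tau_act) * (stim - act)
    if ln is None:
        ln, vn = muscle_geometry(theta, omega, cfg, xp=xp)
    f = muscle_force(act1, ln, vn, cfg, xp=xp)
    tau = f @ cfg.R
    tau1, tau2 = tau[..., 0], tau[..., 1]

    L1, L2 = cfg.link_lengths
    t1 = theta[..., 0]
    t12 = theta[..., 0] + theta[..., 1]
    o1, o2 = omega[..., 0], omega[..., 1]
    if b != 0.0:
        s1, c1 = xp.sin(t1), xp.cos(t1)
        s12, c12 = xp.sin(t12), xp.cos(t12)
        j11 = -L1 * s1 - L2 * s12
        j12 = -L2 * s12
        j21 = L1 * c1 + L2 * c12
        j22 = L2 * c12
        vx = j11 * o1 + j12 * o2
        vy = j21 * o1 + j22 * o2
        fx, fy = -b * vy, b * vx
        tau1 = tau1 + j11 * fx + j21 * fy
        tau2 = tau2 + j12 * fx + j22 * fy

    m1, m2 = cfg.link_masses
    r1, r2 = cfg.com
    I1, I2 = cfg.inertias
    a2 = m2 * L1 * r2
    cth2 = xp.cos(theta[..., 1])
    sth2 = xp.sin(theta[..., 1])
    m22 = I2 + m2 * r2**2
    m11 = I1 + I2 + m1 * r1**2 + m2 * (L1**2 + r2**2) + 2.0 * a2 * cth2
    m12 = m22 + a2 * cth2
    cor1 = -a2 * sth2 * (2.0 * o1 * o2 + o2**2)
    cor2 = a2 * sth2 * o1**2

    tlim = limit_torque(theta, cfg, xp=xp)
    rhs1 = tau1 + tlim[..., 0] - cor1 - cfg.joint_damping * o1
    rhs2 = tau2 + tlim[..., 1] - cor2 - cfg.joint_damping * o2
    det = m11 * m22 - m12 * m12
    dom1 = (m22 * rhs1 - m12 * rhs2) / det
    dom2 = (m11 * rhs2 - m12 * rhs1) / det
    omega1 = omega + dt * xp.stack([dom1, dom2], axis=-1)
    theta1 = theta + dt * omega1
    return theta1, omega1, act1, f


def endpoint_force(state: ArmState, cfg: ArmConfig) -> np.ndarray:
    """Muscle-generated force expressed at the endpoint (excluding the field).

    Solves J^T F = tau with tau = R^T f; raises on a singular Jacobian (the
    fully extended arm).
    """
    return endpoint_force_arrays(
        state.joint_angles, state.muscle_forces, cfg
    )


def endpoint_force_arrays(theta, muscle_forces, cfg: ArmConfig) -> np.ndarray:
    J = jacobian(_arr(theta), cfg)
    tau = _arr(muscle_forces) @ cfg.R
    det = np.linalg.det(J)
    if np.any(np.abs(det) < 1e-10):
        raise np.linalg.LinAlgError("singular endpoint Jacobian (arm fully extended)")
    return np.linalg.solve(np.swapaxes(J, -1, -2), tau[..., None])[..., 0]
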