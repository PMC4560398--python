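"""Numba-compiled simulation kernels.

Everything here operates on plain float64/bool arrays so the whole
3000-step trial loop stays inside compiled code.  The public modules
(:mod:`leadersim.world`, :mod:`leadersim.sensors`,
:mod:`leadersim.controller`) wrap these kernels with typed, documented
interfaces; there is a single implementation of each physical rule.

Angle convention: radians, counter-clockwise positive, 0 along +x,
headings wrapped to [0, 2pi).  Bearings used internally are wrapped to
(-pi, pi].
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi
SECTOR_WIDTH = np.pi / 10.0        # 18 degrees
FOV_LO = -np.pi / 4.0              # retina field of view [-45, +45] degrees
N_SECTORS = 5
N_ROBOTS = 4

# controller geometry: 18 inputs -> 4 hidden -> 2 outputs, 86 parameters
N_INPUTS = 18
N_HIDDEN = 4
N_OUTPUTS = 2
OFF_B1 = N_INPUTS * N_HIDDEN                      # 72
OFF_W2 = OFF_B1 + N_HIDDEN                        # 76
OFF_B2 = OFF_W2 + N_HIDDEN * N_OUTPUTS            # 84
N_PARAMS = OFF_B2 + N_OUTPUTS                     # 86


@njit(cache=True)
def seed_rng(seed):
    """Seed the compiled-code RNG stream.

    Numba's random state is separate from NumPy's; seeding must happen
    inside compiled code to affect the kernels.
    """
    np.random.seed(seed)


@njit(cache=True)
def wrap_2pi(a):
    a = a % TWO_PI
    if a < 0.0:
        a += TWO_PI
    return a


@njit(cache=True)
def wrap_pi(a):
    """Wrap an angle to (-pi, pi]."""
    a = a % TWO_PI
    if a > np.pi:
        a -= TWO_PI
    elif a <= -np.pi:
        a += TWO_PI
    return a


@njit(cache=True)
def step_kinematics_kernel(x, y, th, v_left, v_right, wheelbase):
    """Exact arc integration of the unicycle over one time step.

    Linear speed (v_left+v_right)/2, angular speed (v_right-v_left)/wheelbase.
    Closed form so pure rotation and pure translation are exact.
    """
    v = 0.5 * (v_left + v_right)
    w = (v_right - v_left) / wheelbase
    if abs(w) < 1e-12:
        nx = x + v * np.cos(th)
        ny = y + v * np.sin(th)
        nth = th
    else:
        nth = th + w
        r = v / w
        nx = x + r * (np.sin(nth) - np.sin(th))
        ny = y - r * (np.cos(nth) - np.cos(th))
    return nx, ny, wrap_2pi(nth)


@njit(cache=True)
def retina_kernel(xs, ys, ths, active, observer, colours, radius, out):
    """Fill ``out`` (15,) with the observer's linear-retina activation.

    Each of the 5 photoreceptors covers an 18-degree sector of the
    [-45, +45]-degree field of view (half-open on the right except the
    last).  Another robot subtends the bearing interval
    [bearing - asin(radius/d), bearing + asin(radius/d)]; a sector that
    overlaps at least one robot's interval takes the normalised RGB of
    the *nearest* overlapping robot (occlusion).  No distance limit.
    """
    for k in range(3 * N_SECTORS):
        out[k] = 0.0
    best_d = np.empty(N_SECTORS)
    for k in range(N_SECTORS):
        best_d[k] = np.inf
    for j in range(xs.shape[0]):
        if j == observer or not active[j]:
            continue
        dx = xs[j] - xs[observer]
        dy = ys[j] - ys[observer]
        d = np.sqrt(dx * dx + dy * dy)
        if d <= 0.0:
            continue
        bearing = wrap_pi(np.arctan2(dy, dx) - ths[observer])
        s = radius / d
        if s > 1.0:
            s = 1.0
        alpha = np.arcsin(s)
        # the subtended interval may straddle +-pi; test the three unwrapped copies
        for shift in (-TWO_PI, 0.0, TWO_PI):
            lo = bearing + shift - alpha
            hi = bearing + shift + alpha
            for k in range(N_SECTORS):
                a0 = FOV_LO + k * SECTOR_WIDTH
                a1 = a0 + SECTOR_WIDTH
                if k < N_SECTORS - 1:
                    hit = (lo < a1) and (hi >= a0)
                else:
                    hit = (lo <= a1) and (hi >= a0)
                if hit and d < best_d[k]:
                    best_d[k] = d
                    out[3 * k] = colours[j, 0]
                    out[3 * k + 1] = colours[j, 1]
                    out[3 * k + 2] = colours[j, 2]


@njit(cache=True)
def smell_kernel(x, y, th, zones):
    """Two-line binary code of the quadrant facing the nearest food zone.

    Bearing in [0, 360):  [0, 90) -> (0,1);  [90, 270) -> (1,0);
    [270, 360) -> (1,1).
    """
    best = 0
    best_d2 = np.inf
    for z in range(zones.shape[0]):
        dx = zones[z, 0] - x
        dy = zones[z, 1] - y
        d2 = dx * dx + dy * dy
        if d2 < best_d2:
            best_d2 = d2
            best = z
    bearing = wrap_2pi(np.arctan2(zones[best, 1] - y, zones[best, 0] - x) - th)
    if bearing < 0.5 * np.pi:
        return 0.0, 1.0
    elif bearing < 1.5 * np.pi:
        return 1.0, 0.0
    else:
        return 1.0, 1.0


@njit(cache=True)
def zone_id_kernel(x, y, zones, zone_radius):
    """Index of the food zone whose (open) disc contains (x, y), else -1."""
    r2 = zone_radius * zone_radius
    for z in range(zones.shape[0]):
        dx = x - zones[z, 0]
        dy = y - zones[z, 1]
        if dx * dx + dy * dy < r2:
            return z
    return -1


@njit(cache=True)
def forward_kernel(params, inputs, vmax):
    """Two-layer feed-forward pass, logistic activations.

    Parameter layout (86,): input->hidden weights row-major by input
    index (72), hidden biases (4), hidden->output weights row-major by
    hidden index (8), output biases (2).  Output o in (0,1) maps to
    wheel speed (2o-1)*vmax so o=0.5 is a stopped wheel.
    """
    h = np.empty(N_HIDDEN)
    for j in range(N_HIDDEN):
        s = params[OFF_B1 + j]
        for i in range(N_INPUTS):
            s += inputs[i] * params[i * N_HIDDEN + j]
        h[j] = 1.0 / (1.0 + np.exp(-s))
    o = np.empty(N_OUTPUTS)
    for k in range(N_OUTPUTS):
        s = params[OFF_B2 + k]
        for j in range(N_HIDDEN):
            s += h[j] * params[OFF_W2 + j * N_OUTPUTS + k]
        o[k] = 1.0 / (1.0 + np.exp(-s))
    return (2.0 * o[0] - 1.0) * vmax, (2.0 * o[1] - 1.0) * vmax


@njit(cache=True)
def _inside_walls(x, y, side, radius):
    return (x >= radius) and (x <= side - radius) and (y >= radius) and (y <= side - radius)


@njit(cache=True)
def _clear_of_others(i, x, y, xs, ys, active, diam):
    d2min = diam * diam
    for j in range(xs.shape[0]):
        if j == i or not active[j]:
            continue
        dx = x - xs[j]
        dy = y - ys[j]
        if dx * dx + dy * dy < d2min:
            return False
    return True


@njit(cache=True)
def init_poses_kernel(xs, ys, ths, free, active, side, diam, exclude_zones,
                      zones, zone_radius, max_attempts):
    """Uniform random placement of the free robots, non-overlapping chassis.

    Full-configuration rejection: on any conflict all free robots are
    resampled, so each free robot's marginal position is exactly uniform
    over [radius, side-radius]^2.  Robots with free[i]=False keep their
    preset pose and act as obstacles.  Returns True on success.
    """
    radius = 0.5 * diam
    for _attempt in range(max_attempts):
        for i in range(xs.shape[0]):
            if not free[i] or not active[i]:
                continue
            xs[i] = radius + (side - diam) * np.random.random()
            ys[i] = radius + (side - diam) * np.random.random()
            ths[i] = TWO_PI * np.random.random()
        ok = True
        for i in range(xs.shape[0]):
            if not active[i]:
                continue
            if exclude_zones and free[i] and zone_id_kernel(xs[i], ys[i], zones, zone_radius) >= 0:
                ok = False
                break
            for j in range(i + 1, xs.shape[0]):
                if not active[j]:
                    continue
                dx = xs[i] - xs[j]
                dy = ys[i] - ys[j]
                if dx * dx + dy * dy < diam * diam:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return True
    return False


@njit(cache=True)
def resolve_collisions_kernel(xs, ys, ths, pinned, active, side, diam,
                              displacement, max_attempts, collided_out):
    """Reposition robots that hit a wall or another robot.

    A colliding robot is displaced by ``displacement`` in a uniformly
    random direction (retried until the new spot is legal: chassis fully
    inside the walls and >= one diameter from every other robot) and is
    given a uniform random heading.  Pinned robots are never moved but
    do act as obstacles.

    Resolution sweeps the robots repeatedly: a robot that cannot be
    legally displaced in this sweep (e.g. cornered between a wall and
    two neighbours that have not moved yet) is deferred to the next
    sweep, after the neighbours had their turn.  Returns True once no
    overlap remains, False if the configuration cannot be resolved.
    """
    radius = 0.5 * diam
    n = xs.shape[0]
    for i in range(n):
        collided_out[i] = False
    for _sweep in range(max_attempts):
        any_hit = False
        for i in range(n):
            if not active[i] or pinned[i]:
                continue
            hit = not _inside_walls(xs[i], ys[i], side, radius)
            if not hit:
                hit = not _clear_of_others(i, xs[i], ys[i], xs, ys, active, diam)
            if not hit:
                continue
            any_hit = True
            collided_out[i] = True
            for _a in range(100):
                ang = TWO_PI * np.random.random()
                nx = xs[i] + displacement * np.cos(ang)
                ny = ys[i] + displacement * np.sin(ang)
                if _inside_walls(nx, ny, side, radius) and _clear_of_others(i, nx, ny, xs, ys, active, diam):
                    xs[i] = nx
                    ys[i] = ny
                    ths[i] = TWO_PI * np.random.random()
                    break
        if not any_hit:
            return True
    return False


@njit(cache=True)
def run_trial_kernel(params, pinned, active, pin_x, pin_y, pin_th,
                     steps, side, diam, zones, zone_radius, vmax,
                     displacement, exclude_zones, colours, seed,
                     record_traj, record_sensors):
    """Simulate one trial: sense -> forward -> move -> resolve -> score.

    params: (4, 86) decoded controller parameters per robot.
    Robots with pinned[i] stay motionless at (pin_x, pin_y, pin_th);
    robots with active[i]=False do not exist in the world (removal test).

    Returns (init_pose, pos, ctrl, zone, collided, retina, smell, ground,
    fit_collective, fit_individual).  Poses are logged after movement and
    collision resolution; sensor readings and controls are the ones that
    produced that movement (sensed before any robot moved).  With
    record_traj / record_sensors False the corresponding log arrays come
    back empty (fitness totals are always computed).
    """
    np.random.seed(seed)
    n = params.shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    ths = np.empty(n)
    free = np.empty(n, dtype=np.bool_)
    for i in range(n):
        if pinned[i]:
            xs[i] = pin_x[i]
            ys[i] = pin_y[i]
            ths[i] = pin_th[i]
            free[i] = False
        else:
            xs[i] = -1e6
            ys[i] = -1e6
            ths[i] = 0.0
            free[i] = True
    ok = init_poses_kernel(xs, ys, ths, free, active, side, diam,
                           exclude_zones, zones, zone_radius, 1000)
    if not ok:
        steps = 0  # signalled to the caller by empty logs

    init_pose = np.empty((n, 3))
    for i in range(n):
        init_pose[i, 0] = xs[i]
        init_pose[i, 1] = ys[i]
        init_pose[i, 2] = ths[i]

    n_traj = steps if record_traj else 0
    pos = np.zeros((n_traj, n, 3))
    ctrl = np.zeros((n_traj, n, 2))
    zone = np.full((n_traj, n), -1, dtype=np.int64)
    collided = np.zeros((n_traj, n), dtype=np.bool_)
    n_sense = steps if record_sensors else 0
    retina = np.zeros((n_sense, n, 15))
    smell = np.zeros((n_sense, n, 2))
    ground = np.zeros((n_sense, n))
    fit_col = np.zeros(n)
    fit_ind = np.zeros(n)

    inputs = np.empty(N_INPUTS)
    out15 = np.empty(15)
    vls = np.zeros(n)
    vrs = np.zeros(n)
    coll_row = np.empty(n, dtype=np.bool_)

    for t in range(steps):
        # all robots sense the same pre-move state
        for i in range(n):
            if not active[i]:
                continue
            retina_kernel(xs, ys, ths, active, i, colours, 0.5 * diam, out15)
            s0, s1 = smell_kernel(xs[i], ys[i], ths[i], zones)
            g = 1.0 if zone_id_kernel(xs[i], ys[i], zones, zone_radius) >= 0 else 0.0
            if record_sensors:
                for k in range(15):
                    retina[t, i, k] = out15[k]
                smell[t, i, 0] = s0
                smell[t, i, 1] = s1
                ground[t, i] = g
            if pinned[i]:
                vls[i] = 0.0
                vrs[i] = 0.0
            else:
                for k in range(15):
                    inputs[k] = out15[k]
                inputs[15] = s0
                inputs[16] = s1
                inputs[17] = g
                vls[i], vrs[i] = forward_kernel(params[i], inputs, vmax)
            if record_traj:
                ctrl[t, i, 0] = vls[i]
                ctrl[t, i, 1] = vrs[i]
        for i in range(n):
            if active[i] and not pinned[i]:
                xs[i], ys[i], ths[i] = step_kinematics_kernel(
                    xs[i], ys[i], ths[i], vls[i], vrs[i], diam)
        ok = resolve_collisions_kernel(xs, ys, ths, pinned, active, side,
                                       diam, displacement, 1000, coll_row)
        if not ok:
            break
        all_same = True
        first_zone = -2
        for i in range(n):
            if not active[i]:
                continue
            z = zone_id_kernel(xs[i], ys[i], zones, zone_radius)
            if z >= 0:
                fit_ind[i] += 1.0
            if first_zone == -2:
                first_zone = z
            elif z != first_zone:
                all_same = False
            if record_traj:
                collided[t, i] = coll_row[i]
                zone[t, i] = z
                pos[t, i, 0] = xs[i]
                pos[t, i, 1] = ys[i]
                pos[t, i, 2] = ths[i]
        if all_same and first_zone >= 0:
            for i in range(n):
                if active[i]:
                    fit_col[i] += 1.0
    return init_pose, pos, ctrl, zone, collided, retina, smell, ground, fit_col, fit_ind
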