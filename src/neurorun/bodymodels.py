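"""Built-in full-body model configurations.

Two configurations are provided:

* ``desk_model_config`` -- the default reduced model actually simulated:
  12 segments, 17 joint DOF (yaw-only thoracopelvic revolute, spherical
  shoulders and hips, revolute elbows/knees/ankles) and 34 muscle-tendon
  units grouped into upper-limb, torso and lower-limb sets.

* ``fullscale_model_config`` -- the full 25-joint-DOF layout (spherical
  thoracopelvic/shoulder/hip joints; revolute elbow, knee, ankle, subtalar
  and metatarsophalangeal joints) carrying a 150-muscle roster (92 lower
  limb + torso, 58 upper limb) with schematic two-point paths.  It documents
  the full-scale structure and supports structural operations (DOF counts,
  observation sizing, condition masking); the desk model is the one meant
  for simulation.

Anthropometry defaults to a 65.4 kg, 1.712 m adult; segment masses, lengths
and inertias follow standard cadaver-based proportions scaled to those
values.  Frames: Z up, X forward, Y left; segment frames sit at the proximal
joint with long segments extending along -Z.
"""
from __future__ import annotations

import numpy as np

DEFAULT_MASS = 65.4     # kg
DEFAULT_STATURE = 1.712  # m

# segment mass fractions of total body mass (Winter-style proportions;
# head+neck folded into the torso, hand folded into the forearm)
_MASS_FRAC = {
    "pelvis": 0.142,
    "torso": 0.436,
    "upper_arm": 0.028,
    "forearm": 0.022,
    "thigh": 0.100,
    "shank": 0.0465,
    "foot": 0.0145,
}


def _box_inertia(m, dx, dy, dz):
    return [m * (dy * dy + dz * dz) / 12,
            m * (dx * dx + dz * dz) / 12,
            m * (dx * dx + dy * dy) / 12]


def _rod_inertia(m, length, r_ax=0.03):
    it = m * length * length / 12
    return [it, it, max(m * r_ax * r_ax / 2, 1e-4)]


def _segment_lengths(stature: float) -> dict:
    H = stature
    return {
        "thigh": 0.245 * H,
        "shank": 0.246 * H,
        "foot": 0.152 * H,
        "upper_arm": 0.186 * H,
        "forearm": 0.146 * H,
        "torso": 0.30 * H,
    }


def desk_model_config(total_mass: float = DEFAULT_MASS,
                      stature: float = DEFAULT_STATURE) -> dict:
    """Reduced running model: 6 + 17 DOF, 34 MTUs, 6 contact spheres."""
    M = total_mass
    L = _segment_lengths(stature)
    lt, ls, lf = L["thigh"], L["shank"], L["foot"]
    lua, lfa = L["upper_arm"], L["forearm"]

    bodies = [
        {"name": "pelvis", "mass": _MASS_FRAC["pelvis"] * M,
         "inertia": _box_inertia(_MASS_FRAC["pelvis"] * M, 0.24, 0.30, 0.15),
         "com": [0.0, 0.0, 0.03]},
        {"name": "torso", "mass": _MASS_FRAC["torso"] * M,
         "inertia": _box_inertia(_MASS_FRAC["torso"] * M, 0.28, 0.32, 0.55),
         "com": [0.0, 0.0, 0.22]},
    ]
    joints = [
        {"name": "ground_pelvis", "type": "free6", "child": "pelvis"},
        {"name": "thoraco", "type": "revolute1", "parent": "pelvis", "child": "torso",
         "translation": [-0.03, 0.0, 0.12], "axis": [0, 0, 1],
         "limits_deg": [-30, 30]},
    ]
    sites = [{"name": "head", "body": "torso", "point": [0.0, 0.0, 0.50]}]
    spheres = []
    muscles = []

    for side, ys in (("r", -1.0), ("l", 1.0)):
        ua, fa = f"upper_arm_{side}", f"forearm_{side}"
        th, sh, ft = f"thigh_{side}", f"shank_{side}", f"foot_{side}"
        foot_id = "right" if side == "r" else "left"

        bodies += [
            {"name": ua, "mass": _MASS_FRAC["upper_arm"] * M,
             "inertia": _rod_inertia(_MASS_FRAC["upper_arm"] * M, lua),
             "com": [0.0, 0.0, -0.45 * lua]},
            {"name": fa, "mass": _MASS_FRAC["forearm"] * M,
             "inertia": _rod_inertia(_MASS_FRAC["forearm"] * M, lfa * 1.3),
             "com": [0.0, 0.0, -0.55 * lfa]},
            {"name": th, "mass": _MASS_FRAC["thigh"] * M,
             "inertia": _rod_inertia(_MASS_FRAC["thigh"] * M, lt, 0.05),
             "com": [0.0, 0.0, -0.43 * lt]},
            {"name": sh, "mass": _MASS_FRAC["shank"] * M,
             "inertia": _rod_inertia(_MASS_FRAC["shank"] * M, ls, 0.04),
             "com": [0.0, 0.0, -0.43 * ls]},
            {"name": ft, "mass": _MASS_FRAC["foot"] * M,
             "inertia": [0.002, 0.004, 0.004],
             "com": [0.05, 0.0, -0.04]},
        ]
        joints += [
            {"name": f"shoulder_{side}", "type": "spherical3", "parent": "torso",
             "child": ua, "translation": [0.0, ys * 0.20, 0.36],
             "limits_deg": [[-50, 50], [-80, 80], [-150, 60]]},
            {"name": f"elbow_{side}", "type": "revolute1", "parent": ua,
             "child": fa, "translation": [0.0, 0.0, -lua], "axis": [0, -1, 0],
             "limits_deg": [0, 150]},
            {"name": f"hip_{side}", "type": "spherical3", "parent": "pelvis",
             "child": th, "translation": [0.0, ys * 0.089, -0.06],
             "limits_deg": [[-30, 30], [-40, 40], [-120, 30]]},
            {"name": f"knee_{side}", "type": "revolute1", "parent": th,
             "child": sh, "translation": [0.0, 0.0, -lt], "axis": [0, 1, 0],
             "limits_deg": [0, 150]},
            {"name": f"ankle_{side}", "type": "revolute1", "parent": sh,
             "child": ft, "translation": [0.0, 0.0, -ls], "axis": [0, 1, 0],
             "limits_deg": [-40, 40]},
        ]
        spheres += [
            {"body": ft, "offset": [-0.04, 0.0, -0.05], "radius": 0.03, "foot": foot_id},
            {"body": ft, "offset": [0.62 * lf - 0.04, ys * 0.03, -0.05],
             "radius": 0.025, "foot": foot_id},
            {"body": ft, "offset": [0.62 * lf - 0.04, -ys * 0.03, -0.05],
             "radius": 0.025, "foot": foot_id},
        ]
        sites += [
            {"name": f"hand_{side}", "body": fa, "point": [0.0, 0.0, -1.3 * lfa]},
            {"name": f"foot_{side}", "body": ft, "point": [0.5 * lf, 0.0, -0.05]},
        ]

        def mus(name, f_max, l_opt, path, group="lower_limb"):
            muscles.append({"name": f"{name}_{side}", "f_max": f_max,
                            "l_opt": l_opt, "l_slack": None, "group": group,
                            "path": [{"body": b, "point": list(p)} for b, p in path]})

        # hip
        mus("glut_max", 1600, 0.15, [("pelvis", (-0.08, ys * 0.06, 0.02)),
                                     (th, (-0.035, ys * 0.02, -0.10))])
        mus("iliopsoas", 1300, 0.12, [("pelvis", (0.05, ys * 0.05, 0.02)),
                                      ("pelvis", (0.04, ys * 0.07, -0.05)),
                                      (th, (0.01, ys * 0.01, -0.12))])
        mus("glut_med", 1200, 0.09, [("pelvis", (-0.02, ys * 0.10, 0.03)),
                                     (th, (0.0, ys * 0.045, -0.06))])
        mus("adductors", 1200, 0.12, [("pelvis", (0.02, ys * 0.04, -0.08)),
                                      (th, (0.0, -ys * 0.02, -0.18))])
        # biarticular thigh
        mus("hamstrings", 2200, 0.11, [("pelvis", (-0.07, ys * 0.05, -0.03)),
                                       (sh, (-0.032, 0.0, -0.05))])
        mus("rect_fem", 1200, 0.11, [("pelvis", (0.05, ys * 0.04, -0.02)),
                                     (th, (0.05, 0.0, -0.95 * lt)),
                                     (sh, (0.042, 0.0, -0.06))])
        # knee / ankle
        mus("vasti", 3200, 0.10, [(th, (0.03, 0.0, -0.35 * lt)),
                                  (th, (0.05, 0.0, -0.95 * lt)),
                                  (sh, (0.042, 0.0, -0.06))])
        mus("gastroc", 1800, 0.06, [(th, (-0.02, 0.0, -0.93 * lt)),
                                    (ft, (-0.045, 0.0, -0.04))])
        mus("soleus", 2800, 0.05, [(sh, (-0.02, 0.0, -0.35 * ls)),
                                   (ft, (-0.045, 0.0, -0.04))])
        mus("tib_ant", 1000, 0.07, [(sh, (0.027, 0.0, -0.35 * ls)),
                                    (ft, (0.06, 0.0, -0.01))])
        # torso rotator (one oblique sling per side)
        mus("oblique", 1000, 0.15, [("pelvis", (0.06, ys * 0.09, 0.05)),
                                    ("torso", (0.0, -ys * 0.10, 0.14))], group="torso")
        # shoulder / elbow
        mus("ant_delt", 700, 0.10, [("torso", (0.05, ys * 0.17, 0.34)),
                                    (ua, (0.025, 0.0, -0.30 * lua))], group="upper_limb")
        mus("post_delt", 700, 0.10, [("torso", (-0.05, ys * 0.17, 0.34)),
                                     (ua, (-0.025, 0.0, -0.30 * lua))], group="upper_limb")
        mus("mid_delt", 600, 0.10, [("torso", (0.0, ys * 0.215, 0.38)),
                                    (ua, (0.0, ys * 0.03, -0.25 * lua))], group="upper_limb")
        mus("pect", 800, 0.12, [("torso", (0.04, ys * 0.06, 0.28)),
                                (ua, (0.01, -ys * 0.015, -0.30 * lua))], group="upper_limb")
        mus("biceps", 650, 0.12, [("torso", (0.04, ys * 0.18, 0.35)),
                                  (ua, (0.03, 0.0, -0.55 * lua)),
                                  (fa, (0.022, 0.0, -0.05))], group="upper_limb")
        mus("triceps", 800, 0.12, [("torso", (-0.04, ys * 0.17, 0.33)),
                                   (ua, (-0.025, 0.0, -0.92 * lua)),
                                   (fa, (-0.028, 0.0, -0.03))], group="upper_limb")

    cfg = {
        "schema": 1,
        "name": "desk",
        "gravity": [0.0, 0.0, -9.81],
        "bodies": bodies,
        "joints": joints,
        "contact_spheres": spheres,
        "sites": sites,
        "muscles": muscles,
    }
    _calibrate_slack_lengths(cfg)
    return cfg


def _calibrate_slack_lengths(cfg: dict) -> None:
    """Center each fiber's operating range on its optimal length.

    Muscle-tendon path lengths are sampled over one cycle of the default
    synthetic running motion; tendon slack is set so the fiber sits at its
    optimal length at the mid-range path length, and fibers too short for
    their excursion are widened so normalized length stays within roughly
    [0.3, 1.7] over the cycle.
    """
    from .dynamics import Kinematics
    from .muscle import mtu_length_velocity
    from .reference import GaitParams, generate_reference
    from .skeleton import build_model

    probe = {k: v for k, v in cfg.items() if k != "muscles"}
    model = build_model(probe)
    ref = generate_reference(GaitParams(), model, fit_ground=False)
    u0 = np.zeros(model.n_u)
    kins = []
    for phi in np.linspace(0.0, 1.0, 24, endpoint=False):
        st = ref.gen_state(model, phi * ref.cycle_T)
        kins.append(Kinematics(model, st.q, u0))
    for m in cfg["muscles"]:
        path = [(p["body"], np.asarray(p["point"])) for p in m["path"]]
        lens = [mtu_length_velocity(model, None, u0, path, kin=k)[0] for k in kins]
        lmin, lmax = min(lens), max(lens)
        l_opt = max(m["l_opt"], 0.7 * (lmax - lmin))
        slack = 0.5 * (lmin + lmax) - l_opt
        if slack < 0.005:
            slack = 0.005
            l_opt = 0.5 * (lmin + lmax) - slack
        m["l_opt"] = float(l_opt)
        m["l_slack"] = float(slack)


# ---------------------------------------------------------------------------
# full-scale roster
# ---------------------------------------------------------------------------

_GAIT_LOWER = [
    # (name, proximal segment key, distal segment key)
    *[(f"glut_med{i}", "pelvis", "thigh") for i in (1, 2, 3)],
    *[(f"glut_min{i}", "pelvis", "thigh") for i in (1, 2, 3)],
    ("semimem", "pelvis", "shank"), ("semiten", "pelvis", "shank"),
    ("bifemlh", "pelvis", "shank"), ("bifemsh", "thigh", "shank"),
    ("sar", "pelvis", "shank"), ("add_long", "pelvis", "thigh"),
    ("add_brev", "pelvis", "thigh"),
    *[(f"add_mag{i}", "pelvis", "thigh") for i in (1, 2, 3)],
    ("tfl", "pelvis", "thigh"), ("pect", "pelvis", "thigh"),
    ("grac", "pelvis", "shank"),
    *[(f"glut_max{i}", "pelvis", "thigh") for i in (1, 2, 3)],
    ("iliacus", "pelvis", "thigh"), ("psoas", "pelvis", "thigh"),
    ("quad_fem", "pelvis", "thigh"), ("gem", "pelvis", "thigh"),
    ("peri", "pelvis", "thigh"), ("rect_fem", "pelvis", "shank"),
    ("vas_med", "thigh", "shank"), ("vas_int", "thigh", "shank"),
    ("vas_lat", "thigh", "shank"),
    ("med_gas", "thigh", "calcn"), ("lat_gas", "thigh", "calcn"),
    ("soleus", "shank", "calcn"), ("tib_post", "shank", "calcn"),
    ("flex_dig", "shank", "toes"), ("flex_hal", "shank", "toes"),
    ("tib_ant", "shank", "calcn"), ("per_brev", "shank", "calcn"),
    ("per_long", "shank", "calcn"), ("per_tert", "shank", "calcn"),
    ("ext_dig", "shank", "toes"), ("ext_hal", "shank", "toes"),
]
_TORSO_MUSCLES = [("ercspn", "pelvis", "torso"), ("intobl", "pelvis", "torso"),
                  ("extobl", "pelvis", "torso")]
_UPPER = [
    ("delt_ant", "torso", "upper_arm"), ("delt_mid", "torso", "upper_arm"),
    ("delt_post", "torso", "upper_arm"), ("supraspinatus", "torso", "upper_arm"),
    ("infraspinatus", "torso", "upper_arm"), ("subscapularis", "torso", "upper_arm"),
    ("teres_minor", "torso", "upper_arm"), ("teres_major", "torso", "upper_arm"),
    ("pec_maj_c", "torso", "upper_arm"), ("pec_maj_s", "torso", "upper_arm"),
    ("pec_maj_r", "torso", "upper_arm"), ("lat_dorsi_c", "torso", "upper_arm"),
    ("lat_dorsi_s", "torso", "upper_arm"), ("lat_dorsi_r", "torso", "upper_arm"),
    ("coracobrachialis", "torso", "upper_arm"), ("bic_long", "torso", "forearm"),
    ("bic_short", "torso", "forearm"), ("tri_long", "torso", "forearm"),
    ("tri_lat", "upper_arm", "forearm"), ("tri_med", "upper_arm", "forearm"),
    ("brachialis", "upper_arm", "forearm"), ("brachioradialis", "upper_arm", "forearm"),
    ("anconeus", "upper_arm", "forearm"), ("supinator", "upper_arm", "forearm"),
    ("pron_teres", "upper_arm", "forearm"), ("pron_quad", "forearm", "forearm_d"),
    ("fcr", "upper_arm", "forearm_d"), ("fcu", "upper_arm", "forearm_d"),
    ("ecrl", "upper_arm", "forearm_d"),
]


def fullscale_model_config(total_mass: float = DEFAULT_MASS,
                           stature: float = DEFAULT_STATURE) -> dict:
    """Full 25-joint-DOF layout with the 150-muscle roster (schematic paths)."""
    M = total_mass
    L = _segment_lengths(stature)
    lt, ls, lf = L["thigh"], L["shank"], L["foot"]
    lua, lfa = L["upper_arm"], L["forearm"]
    foot_m = _MASS_FRAC["foot"] * M

    bodies = [
        {"name": "pelvis", "mass": _MASS_FRAC["pelvis"] * M,
         "inertia": _box_inertia(_MASS_FRAC["pelvis"] * M, 0.24, 0.30, 0.15),
         "com": [0.0, 0.0, 0.03]},
        {"name": "torso", "mass": _MASS_FRAC["torso"] * M,
         "inertia": _box_inertia(_MASS_FRAC["torso"] * M, 0.28, 0.32, 0.55),
         "com": [0.0, 0.0, 0.22]},
    ]
    joints = [
        {"name": "ground_pelvis", "type": "free6", "child": "pelvis"},
        {"name": "thoraco", "type": "spherical3", "parent": "pelvis",
         "child": "torso", "translation": [-0.03, 0.0, 0.12]},
    ]
    spheres, sites, muscles = [], [{"name": "head", "body": "torso", "point": [0, 0, 0.50]}], []

    for side, ys in (("r", -1.0), ("l", 1.0)):
        seg = {
            "pelvis": "pelvis", "torso": "torso",
            "upper_arm": f"upper_arm_{side}", "forearm": f"forearm_{side}",
            "forearm_d": f"forearm_{side}",
            "thigh": f"thigh_{side}", "shank": f"shank_{side}",
            "talus": f"talus_{side}", "calcn": f"calcn_{side}", "toes": f"toes_{side}",
        }
        foot_id = "right" if side == "r" else "left"
        bodies += [
            {"name": seg["upper_arm"], "mass": _MASS_FRAC["upper_arm"] * M,
             "inertia": _rod_inertia(_MASS_FRAC["upper_arm"] * M, lua),
             "com": [0, 0, -0.45 * lua]},
            {"name": seg["forearm"], "mass": _MASS_FRAC["forearm"] * M,
             "inertia": _rod_inertia(_MASS_FRAC["forearm"] * M, lfa * 1.3),
             "com": [0, 0, -0.55 * lfa]},
            {"name": seg["thigh"], "mass": _MASS_FRAC["thigh"] * M,
             "inertia": _rod_inertia(_MASS_FRAC["thigh"] * M, lt, 0.05),
             "com": [0, 0, -0.43 * lt]},
            {"name": seg["shank"], "mass": _MASS_FRAC["shank"] * M,
             "inertia": _rod_inertia(_MASS_FRAC["shank"] * M, ls, 0.04),
             "com": [0, 0, -0.43 * ls]},
            {"name": seg["talus"], "mass": 0.1 * foot_m,
             "inertia": [1e-4, 1e-4, 1e-4], "com": [0, 0, 0]},
            {"name": seg["calcn"], "mass": 0.7 * foot_m,
             "inertia": [0.0015, 0.003, 0.003], "com": [0.06, 0, -0.03]},
            {"name": seg["toes"], "mass": 0.2 * foot_m,
             "inertia": [2e-4, 2e-4, 2e-4], "com": [0.02, 0, 0]},
        ]
        joints += [
            {"name": f"shoulder_{side}", "type": "spherical3", "parent": "torso",
             "child": seg["upper_arm"], "translation": [0, ys * 0.20, 0.36]},
            {"name": f"elbow_{side}", "type": "revolute1", "parent": seg["upper_arm"],
             "child": seg["forearm"], "translation": [0, 0, -lua],
             "axis": [0, -1, 0], "limits_deg": [0, 150]},
            {"name": f"hip_{side}", "type": "spherical3", "parent": "pelvis",
             "child": seg["thigh"], "translation": [0, ys * 0.089, -0.06]},
            {"name": f"knee_{side}", "type": "revolute1", "parent": seg["thigh"],
             "child": seg["shank"], "translation": [0, 0, -lt],
             "axis": [0, 1, 0], "limits_deg": [0, 150]},
            {"name": f"ankle_{side}", "type": "revolute1", "parent": seg["shank"],
             "child": seg["talus"], "translation": [0, 0, -ls],
             "axis": [0, 1, 0], "limits_deg": [-40, 40]},
            {"name": f"subtalar_{side}", "type": "revolute1", "parent": seg["talus"],
             "child": seg["calcn"], "translation": [-0.04, 0, -0.04],
             "axis": [1, 0, 0], "limits_deg": [-25, 25]},
            {"name": f"mtp_{side}", "type": "revolute1", "parent": seg["calcn"],
             "child": seg["toes"], "translation": [0.65 * lf, 0, 0],
             "axis": [0, 1, 0], "limits_deg": [-30, 60]},
        ]
        spheres += [
            {"body": seg["calcn"], "offset": [0.0, 0, -0.01], "radius": 0.03,
             "foot": foot_id},
            {"body": seg["toes"], "offset": [0.02, ys * 0.025, -0.01],
             "radius": 0.02, "foot": foot_id},
            {"body": seg["toes"], "offset": [0.02, -ys * 0.025, -0.01],
             "radius": 0.02, "foot": foot_id},
        ]
        sites += [
            {"name": f"hand_{side}", "body": seg["forearm"], "point": [0, 0, -1.3 * lfa]},
            {"name": f"foot_{side}", "body": seg["calcn"], "point": [0.4 * lf, 0, -0.03]},
        ]

        def _schematic(name, a, b, group):
            muscles.append({
                "name": f"{name}_{side}", "f_max": 1000.0, "l_opt": 0.10,
                "l_slack": 0.15, "group": group,
                "path": [{"body": seg[a], "point": [0.02, ys * 0.02, -0.05]},
                         {"body": seg[b], "point": [-0.02, ys * 0.01, -0.05]}],
            })

        for name, a, b in _GAIT_LOWER:
            _schematic(name, a, b, "lower_limb")
        for name, a, b in _TORSO_MUSCLES:
            _schematic(name, a, b, "torso")
        for name, a, b in _UPPER:
            _schematic(name, a, b, "upper_limb")

    return {
        "schema": 1,
        "name": "fullscale",
        "gravity": [0.0, 0.0, -9.81],
        "bodies": bodies,
        "joints": joints,
        "contact_spheres": spheres,
        "sites": sites,
        "muscles": muscles,
    }


def builtin_model_config(name: str, **kw) -> dict:
    if name == "desk":
        return desk_model_config(**kw)
    if name == "fullscale":
        return fullscale_model_config(**kw)
    raise KeyError(f"unknown builtin model {name!r}")
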