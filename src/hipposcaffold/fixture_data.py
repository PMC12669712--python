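"""Access to the packaged condition fixtures (effect profiles, qPCR designs,
an example signed-interaction table)."""

from __future__ import annotations

from importlib import resources

from .synthetic import CTDesign, EffectProfile

PROFILE_NAMES = ("wt", "ksr1_null", "ksr1_oe")
CT_DESIGN_NAMES = (
    "mef_ko_cyr61", "mef_ko_ctgf", "mef_oe_yap", "mef_ko_yap", "mcf7_kd_yap",
)


def fixture_path(filename: str):
    """Filesystem path of a packaged fixture file (context-manager free for
    an installed, unzipped package)."""
    ref = resources.files("hipposcaffold.fixtures") / filename
    return ref


def load_profile(name: str) -> EffectProfile:
    if name not in PROFILE_NAMES:
        raise ValueError(f"unknown profile {name!r}; available: {PROFILE_NAMES}")
    with resources.as_file(fixture_path(f"{name}.yaml")) as path:
        return EffectProfile.from_yaml(path)


def load_ct_design(name: str) -> CTDesign:
    if name not in CT_DESIGN_NAMES:
        raise ValueError(f"unknown design {name!r}; available: {CT_DESIGN_NAMES}")
    with resources.as_file(fixture_path(f"{name}.yaml")) as path:
        return CTDesign.from_yaml(path)
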