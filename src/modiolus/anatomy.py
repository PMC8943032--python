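"""Convenience constructors for individualized wall-spiral pairs."""

from __future__ import annotations

from functools import lru_cache

from .spiral import SpiralTemplate, WallSpiral, load_template, project_height, scale_template

__all__ = ["mean_anatomy", "individualize", "CORROSION_MEANS"]

#: corrosion-cast population means of (A_lat, B_lat, A_mod, B_mod) in mm
CORROSION_MEANS = {"A_lat": 9.24, "B_lat": 6.80, "A_mod": 5.46, "B_mod": 3.17}


@lru_cache(maxsize=2)
def _templates() -> tuple[SpiralTemplate, SpiralTemplate]:
    return load_template("modiolar_mean"), load_template("lateral_mean")


def individualize(
    A_lat: float, B_lat: float, A_mod: float, B_mod: float
) -> tuple[WallSpiral, WallSpiral]:
    """Scale the packaged templates to one cochlea's measures.

    Returns ``(modiolar, lateral)`` wall spirals; the modiolar spiral
    carries the lateral wall's (better characterized) height profile.
    """
    mod_t, lat_t = _templates()
    lateral = scale_template(lat_t, A_lat, B_lat)
    modiolar = project_height(lateral, scale_template(mod_t, A_mod, B_mod))
    return modiolar, lateral


def mean_anatomy() -> tuple[WallSpiral, WallSpiral]:
    """The mean corrosion-cast anatomy (modiolar, lateral wall spirals)."""
    return individualize(**CORROSION_MEANS)
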