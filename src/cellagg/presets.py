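"""Published simulation parameter sets for the two glioma cell lines.

Step lengths are given in pixel lengths (0.658 µm per pixel) as in the
figure captions; `alpha_max` and the proliferation rate are per cell
line (F98: 0.7 and 7e-4 /min with compaction; U87: 0.2 and 3e-4 /min
without compaction).  The flux bias is on for the non-adhesive gels and
off for the adhesive ones.
"""

from __future__ import annotations

from .engine import AbmConfig, FluxSpec, PIXEL_SIZE_UM

__all__ = ["f98_config", "u87_config", "PRESETS"]


def f98_config(
    n_initial: int = 784,
    step_length_px: float = 6.0,
    flux_on: bool = True,
    **overrides,
) -> AbmConfig:
    """F98 cell line (13.2 µm diameter, compacting aggregates).

    Defaults reproduce the non-adhesive condition; the adhesive one used
    e.g. step 1.6 px, 484 cells, flux off.
    """
    kw = dict(
        n_initial=n_initial,
        cell_diameter=13.2,
        step_length=step_length_px * PIXEL_SIZE_UM,
        proliferation_rate=7e-4,
        alpha_max=0.7,
        compaction_enabled=True,
        flux=FluxSpec(enabled=flux_on),
    )
    kw.update(overrides)
    return AbmConfig(**kw)


def u87_config(
    n_initial: int = 625,
    step_length_px: float = 6.0,
    flux_on: bool = False,
    **overrides,
) -> AbmConfig:
    """U87 cell line (21.1 µm diameter, loose non-compacting aggregates)."""
    kw = dict(
        n_initial=n_initial,
        cell_diameter=21.1,
        step_length=step_length_px * PIXEL_SIZE_UM,
        proliferation_rate=3e-4,
        alpha_max=0.2,
        compaction_enabled=False,
        flux=FluxSpec(enabled=flux_on),
    )
    kw.update(overrides)
    return AbmConfig(**kw)


#: named fitted configurations from the published comparison figures
PRESETS = {
    "f98_nonadhesive": lambda: f98_config(n_initial=784, step_length_px=6.0, flux_on=True),
    "f98_adhesive": lambda: f98_config(n_initial=484, step_length_px=1.6, flux_on=False),
    "u87_nonadhesive": lambda: u87_config(n_initial=625, step_length_px=6.0, flux_on=False),
    "u87_adhesive": lambda: u87_config(n_initial=484, step_length_px=2.0, flux_on=False),
}
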