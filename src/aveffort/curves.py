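"""Quadratic effort curves over SNR and their analytic vertices.

Listening effort (indexed by peak pupil dilation or frontal midline theta
power) is modelled as a concave quadratic in signal-to-noise ratio, with the
audiovisual (AV) modality allowed to differ from auditory-only (AO) in
offset, slope, and curvature.  On the centered SNR scale ``x = snr - center``::

    effort_AO(x) = b0 + b1*x + b2*x**2
    effort_AV(x) = (b0 + m0) + (b1 + m1)*x + (b2 + m2)*x**2

The SNR at which effort peaks (the vertex of the parabola) is ``-b1/(2*b2)``
for AO and ``-(b1 + m1)/(2*(b2 + m2))`` for AV; the *peak shift*
``Peak_AO - Peak_AV`` is positive when the AV curve peaks at a harder SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EffortCurveParams",
    "effort_curve",
    "DEFAULT_PUPIL_PARAMS",
    "DEFAULT_THETA_PARAMS",
    "params_with_true_shift",
]

#: Modalities that carry an effort curve.  The visual-only condition has no
#: SNR manipulation and is handled with a fixed effort level elsewhere.
CURVE_MODALITIES = ("AO", "AV")


@dataclass(frozen=True)
class EffortCurveParams:
    """Fixed-effect structure of the quadratic effort model.

    Units are "response units": millimetres of pupil dilation for the pupil
    curve, dB of baseline-relative theta power for the EEG curve.  ``linear``
    and ``quad`` are per dB and per dB**2 on the centered SNR scale; the
    ``mod_*`` terms are AV-minus-AO offsets of the same coefficients.
    """

    intercept: float
    linear: float
    quad: float
    mod_offset: float = 0.0
    mod_linear: float = 0.0
    mod_quad: float = 0.0
    center_snr: float = -6.0

    def validate(self, require_concave: bool = True) -> None:
        if require_concave and not (self.quad < 0 and self.quad + self.mod_quad < 0):
            raise ValueError(
                "effort curves must be concave: quad and quad + mod_quad "
                f"must be < 0 (got {self.quad} and {self.quad + self.mod_quad})"
            )

    def coefficients(self, modality: str) -> tuple[float, float, float]:
        """Return (b0, b1, b2) of the quadratic for one modality."""
        _check_modality(modality)
        if modality == "AV":
            return (
                self.intercept + self.mod_offset,
                self.linear + self.mod_linear,
                self.quad + self.mod_quad,
            )
        return (self.intercept, self.linear, self.quad)

    def vertex_centered(self, modality: str) -> float:
        """Peak SNR on the centered scale, ``-b1 / (2 b2)``."""
        _, b1, b2 = self.coefficients(modality)
        if b2 == 0:
            raise ValueError(f"vertex undefined: zero quadratic coefficient for {modality}")
        return -b1 / (2.0 * b2)

    def vertex_db(self, modality: str) -> float:
        """Peak SNR in raw dB (centered vertex plus the centering constant)."""
        return self.vertex_centered(modality) + self.center_snr

    @property
    def true_shift_db(self) -> float:
        """Ground-truth peak shift Peak_AO - Peak_AV in dB."""
        return self.vertex_centered("AO") - self.vertex_centered("AV")


def _check_modality(modality: str) -> None:
    if modality not in CURVE_MODALITIES:
        raise ValueError(f"modality must be one of {CURVE_MODALITIES}, got {modality!r}")


def effort_curve(snr_db, modality: str, params: EffortCurveParams):
    """Evaluate the effort curve at ``snr_db`` (raw dB scale) for a modality.

    Deterministic and vectorised over ``snr_db``.
    """
    b0, b1, b2 = params.coefficients(modality)
    x = np.asarray(snr_db, dtype=float) - params.center_snr
    out = b0 + b1 * x + b2 * x * x
    return out if out.ndim else float(out)


def params_with_true_shift(base: EffortCurveParams, shift_db: float) -> EffortCurveParams:
    """Adjust ``mod_linear`` so the ground-truth peak shift equals ``shift_db``.

    Keeps every other coefficient (including ``mod_quad``) at its base value,
    so the AO curve and the AV curvature are untouched.
    """
    target_av_vertex = base.vertex_centered("AO") - shift_db
    q_av = base.quad + base.mod_quad
    mod_linear = -2.0 * q_av * target_av_vertex - base.linear
    return replace(base, mod_linear=mod_linear)


#: Pupil-dilation curve (mm).  Slope/curvature and the modality interactions
#: follow the fitted group-level pupil model this package reproduces
#: (AO vertex at -4.5 dB SNR, AV vertex at -7.25 dB, peak shift 2.75 dB).
DEFAULT_PUPIL_PARAMS = EffortCurveParams(
    intercept=0.25,
    linear=0.003,
    quad=-0.001,
    mod_offset=0.05,
    mod_linear=-0.005,
    mod_quad=2e-4,
)

#: Frontal midline theta curve (dB re baseline).  Curvature matches the
#: group-level theta model; the modality slope offset is chosen so the
#: ground-truth peak shift is 0.86 dB with no overall modality offset
#: (the theta modality main effect is not reliably nonzero).
DEFAULT_THETA_PARAMS = EffortCurveParams(
    intercept=0.5,
    linear=0.006,
    quad=-0.002,
    mod_offset=0.0,
    mod_linear=-0.00344,
    mod_quad=0.0,
)
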