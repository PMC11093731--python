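"""Canopy-level radiative transfer: four-stream turbid-medium model.

Couples leaf hemispherical optics with leaf area index, a two-parameter
trigonometric leaf-inclination distribution, a hotspot correction and
sun/view geometry over a reflecting soil background, and returns the
top-of-canopy bidirectional reflectance factor.  The four streams are the
direct solar flux, the direct flux in the view direction, and the upward
and downward diffuse fluxes; the diffuse system is solved analytically per
wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import WAVELENGTHS, default_soil_spectrum
from .prospect import SpectralSample

#: Named leaf-angle-distribution presets: (lidf_a, lidf_b)
LIDF_PRESETS = {
    "spherical": (-0.35, -0.15),
    "planophile": (1.0, 0.0),
    "erectophile": (-1.0, 0.0),
    "plagiophile": (0.0, -1.0),
    "uniform": (0.0, 0.0),
}


@dataclass(frozen=True)
class CanopyParams:
    """Canopy structure, geometry and background.

    Defaults are the fixed retrieval values: spherical-like leaf angle
    distribution (a -0.35, b -0.15), hotspot 0.01, solar zenith 30 deg,
    view zenith 10 deg, relative azimuth 0 deg; the soil background
    defaults to the bundled synthetic dry-soil spectrum.
    """

    lai: float = 3.0
    lidf_a: float = -0.35
    lidf_b: float = -0.15
    hspot: float = 0.01
    tts: float = 30.0  # solar zenith, degrees
    tto: float = 10.0  # view zenith, degrees
    psi: float = 0.0   # relative azimuth, degrees
    soil_reflectance: np.ndarray = field(default_factory=default_soil_spectrum)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lai <= 8.0:
            raise ValueError(f"lai must be within [0, 8], got {self.lai}")
        if not -1.0 <= self.lidf_a <= 1.0 or not -1.0 <= self.lidf_b <= 1.0:
            raise ValueError("lidf_a and lidf_b must lie in [-1, 1]")
        if not 0.0 <= self.tts < 90.0 or not 0.0 <= self.tto < 90.0:
            raise ValueError("zenith angles must lie in [0, 90) degrees")
        if self.hspot < 0:
            raise ValueError("hspot must be non-negative")
        if np.asarray(self.soil_reflectance).shape != WAVELENGTHS.shape:
            raise ValueError("soil_reflectance must be on the 400-2500 nm 1 nm grid")


def leaf_inclination_distribution(
    lidf_a: float, lidf_b: float, n_angles: int = 13
) -> tuple[np.ndarray, np.ndarray]:
    """Leaf-angle frequencies for the two-parameter trigonometric family.

    Returns (midpoint angles in degrees, frequency per bin).  The bins are
    the conventional 13: nine 10-degree bins to 80 degrees then four
    2.5-degree bins to 90.
    """

    def cumulative(theta_deg: float) -> float:
        if theta_deg >= 90.0:
            return 1.0
        if lidf_a > 1.0 - 1e-9 and abs(lidf_b) < 1e-9:
            return 1.0 - np.cos(np.radians(theta_deg))
        x = 2.0 * np.radians(theta_deg)
        p = x
        y = 0.0
        for _ in range(200):
            y = lidf_a * np.sin(x) + 0.5 * lidf_b * np.sin(2.0 * x)
            dx = 0.5 * (y - x + p)
            x += dx
            if abs(dx) < 1e-9:
                break
        return (2.0 * y + p) / np.pi

    bounds = np.concatenate([np.arange(0.0, 81.0, 10.0), [82.5, 85.0, 87.5, 90.0]])
    cum = np.array([cumulative(b) for b in bounds])
    freq = np.diff(cum)
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    return mids, freq


def _volume_scattering(tts: float, tto: float, psi: float, ttl: float):
    """Geometric factors for one leaf-inclination angle: fractions of leaf
    area projected toward sun/view and the bidirectional scattering terms."""
    cts, cto = np.cos(np.radians(tts)), np.cos(np.radians(tto))
    sts, sto = np.sin(np.radians(tts)), np.sin(np.radians(tto))
    psir = np.radians(psi)
    cttl, sttl = np.cos(np.radians(ttl)), np.sin(np.radians(ttl))
    cs, co = cttl * cts, cttl * cto
    ss, so = sttl * sts, sttl * sto

    cosbts = -cs / ss if abs(ss) > 1e-6 else 5.0
    cosbto = -co / so if abs(so) > 1e-6 else 5.0

    if abs(cosbts) < 1.0:
        bts, ds = np.arccos(cosbts), ss
    else:
        bts, ds = np.pi, cs
    chi_s = 2.0 / np.pi * ((bts - np.pi * 0.5) * cs + np.sin(bts) * ss)

    if abs(cosbto) < 1.0:
        bto, do_ = np.arccos(cosbto), so
    elif tto < 90.0:
        bto, do_ = np.pi, co
    else:
        bto, do_ = 0.0, -co
    chi_o = 2.0 / np.pi * ((bto - np.pi * 0.5) * co + np.sin(bto) * so)

    btran1 = abs(bts - bto)
    btran2 = np.pi - abs(bts + bto - np.pi)
    if psir <= btran1:
        bt1, bt2, bt3 = psir, btran1, btran2
    elif psir <= btran2:
        bt1, bt2, bt3 = btran1, psir, btran2
    else:
        bt1, bt2, bt3 = btran1, btran2, psir

    t1 = 2.0 * cs * co + ss * so * np.cos(psir)
    t2 = 0.0
    if bt2 > 0.0:
        t2 = np.sin(bt2) * (2.0 * ds * do_ + ss * so * np.cos(bt1) * np.cos(bt3))
    denom = 2.0 * np.pi**2
    frho = max((np.pi - bt2) * t1 + t2, 0.0) / denom
    ftau = max(-bt2 * t1 + t2, 0.0) / denom
    return chi_s, chi_o, frho, ftau


def _j1(k, l, t):
    # (e^{-lt} - e^{-kt}) / (k - l), stable near k = l
    k = np.asarray(k, dtype=float)
    l = np.asarray(l, dtype=float)
    delta = (k - l) * t
    out = np.where(
        np.abs(delta) > 1e-3,
        (np.exp(-l * t) - np.exp(-k * t)) / np.where(np.abs(k - l) > 1e-30, k - l, 1.0),
        0.5 * t * (np.exp(-k * t) + np.exp(-l * t)) * (1.0 - delta**2 / 12.0),
    )
    return out


def _j2(k, l, t):
    return (1.0 - np.exp(-(k + l) * t)) / (k + l)


def _hotspot(alf: float, lai: float, ks: float, ko: float):
    """Bidirectional gap-probability integral with hotspot correction.

    Returns (tsstoo, sumint): the joint sun+view gap probability and the
    integral entering the single-scattering term.
    """
    if alf == 0.0:
        # observation exactly in the hotspot direction
        tss = np.exp(-ks * lai)
        return tss, (1.0 - tss) / (ks * lai)
    fhot = lai * np.sqrt(ko * ks)
    x1, y1, f1 = 0.0, 0.0, 1.0
    fint = (1.0 - np.exp(-alf)) * 0.05
    sumint = 0.0
    for istep in range(1, 21):
        x2 = 1.0 if istep == 20 else -np.log(1.0 - istep * fint) / alf
        y2 = -(ko + ks) * lai * x2 + fhot * (1.0 - np.exp(-alf * x2)) / alf
        f2 = np.exp(y2)
        sumint += (f2 - f1) * (x2 - x1) / (y2 - y1)
        x1, y1, f1 = x2, y2, f2
    return f1, sumint


def sail_canopy(leaf: SpectralSample, canopy: CanopyParams) -> SpectralSample:
    """Top-of-canopy bidirectional reflectance factor on the 1 nm grid.

    With ``lai = 0`` the canopy is transparent and the output equals the
    soil background exactly.
    """
    rho = np.asarray(leaf.reflectance, dtype=float)
    if leaf.transmittance is None:
        raise ValueError("leaf sample must carry transmittance for canopy simulation")
    tau = np.asarray(leaf.transmittance, dtype=float)
    rsoil = np.asarray(canopy.soil_reflectance, dtype=float)
    lai = canopy.lai
    if lai <= 0.0:
        return SpectralSample(reflectance=rsoil.copy())

    tts, tto, psi = canopy.tts, canopy.tto, canopy.psi
    cts, cto = np.cos(np.radians(tts)), np.cos(np.radians(tto))

    mids, freq = leaf_inclination_distribution(canopy.lidf_a, canopy.lidf_b)
    ks = ko = bf = sob = sof = 0.0
    for ttl, f in zip(mids, freq):
        chi_s, chi_o, frho, ftau = _volume_scattering(tts, tto, psi, ttl)
        ks += chi_s / cts * f
        ko += chi_o / cto * f
        bf += np.cos(np.radians(ttl)) ** 2 * f
        sob += frho * np.pi / (cts * cto) * f
        sof += ftau * np.pi / (cts * cto) * f

    sdb, sdf = 0.5 * (ks + bf), 0.5 * (ks - bf)
    dob, dof = 0.5 * (ko + bf), 0.5 * (ko - bf)
    ddb, ddf = 0.5 * (1.0 + bf), 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    m = np.sqrt(np.maximum((att + sigb) * (att - sigb), 1e-30))
    sb, sf = sdb * rho + sdf * tau, sdf * rho + sdb * tau
    vb, vf = dob * rho + dof * tau, dof * rho + dob * tau
    w = sob * rho + sof * tau

    e1 = np.exp(-m * lai)
    e2 = e1**2
    rinf = np.where(sigb > 1e-30, (att - m) / np.maximum(sigb, 1e-30), 0.0)
    rinf2 = rinf**2
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    J1ks = _j1(ks, m, lai)
    J1ko = _j1(ko, m, lai)

    Ps = (sf + sb * rinf) * J1ks
    Qs = (sf * rinf + sb) * _j2(ks, m, lai)
    Pv = (vf + vb * rinf) * J1ko
    Qv = (vf * rinf + vb) * _j2(ko, m, lai)

    rdd = rinf * (1.0 - e2) / denom
    tdd = (1.0 - rinf2) * e1 / denom
    tsd = (Ps - re * Qs) / denom
    rsd = (Qs - re * Ps) / denom
    tdo = (Pv - re * Qv) / denom
    rdo = (Qv - re * Pv) / denom

    tss = np.exp(-ks * lai)
    too = np.exp(-ko * lai)

    # multiple-scattering contribution to the bidirectional term
    z = _j2(ks, ko, lai)
    T1 = (z - J1ks * too) / (ko + m)
    T2 = (z - J1ko * tss) / (ks + m)
    T3 = (vf * rinf + vb) * T1
    T4 = (vf + vb * rinf) * T2
    T5 = T3 * (sf + sb * rinf)
    T6 = T4 * (sf * rinf + sb)
    T7 = (rdo * Qs + tdo * Ps) * rinf
    rsod = (T5 + T6 - T7) / (1.0 - rinf2)

    # single-scattering contribution with hotspot
    dso = np.sqrt(
        np.tan(np.radians(tts)) ** 2
        + np.tan(np.radians(tto)) ** 2
        - 2.0 * np.tan(np.radians(tts)) * np.tan(np.radians(tto)) * np.cos(np.radians(psi))
    )
    alf = 1e6
    if canopy.hspot > 0:
        alf = dso / canopy.hspot * 2.0 / (ks + ko)
    if dso == 0.0:
        alf = 0.0
    tsstoo, sumint = _hotspot(alf, lai, ks, ko)
    rsos = w * lai * sumint

    # combine with the soil lower boundary
    dn = 1.0 - rsoil * rdd
    rsodt = rsod + ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn
    rsost = rsos + tsstoo * rsoil
    rsot = rsost + rsodt
    return SpectralSample(reflectance=np.clip(rsot, 0.0, 1.0))
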