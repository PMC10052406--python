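"""CT dose arithmetic for protocol reporting.

DLP = CTDIvol x scan length; effective dose E = k x DLP, where k is the
body-region conversion factor in mSv/(mGy.cm) -- 0.015 for the pelvis per
the AAPM recommendation, but always an explicit input because it changes
with the scanned region.  Raw products are returned unrounded; rounding
(half-up, 3 significant figures for DLP, 2 decimals for E) happens only in
the reporting layer.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["PELVIS_K", "dlp", "effective_dose", "dose_report",
           "round_sig", "round_dp"]

#: AAPM pelvis conversion factor, mSv per mGy.cm.
PELVIS_K = 0.015


def _check_non_negative(**kwargs) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def dlp(ctdi_vol: float, scan_length: float) -> float:
    """Dose-length product (mGy.cm) = CTDIvol (mGy) x scan length (cm)."""
    _check_non_negative(ctdi_vol=ctdi_vol, scan_length=scan_length)
    return ctdi_vol * scan_length


def effective_dose(dlp_value: float, k: float) -> float:
    """Effective dose (mSv) = k (mSv/(mGy.cm)) x DLP (mGy.cm)."""
    _check_non_negative(dlp=dlp_value, k=k)
    return k * dlp_value


def round_sig(x: float, figures: int) -> float:
    """Half-up rounding to ``figures`` significant figures."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    exponent = d.adjusted() - figures + 1
    return float(d.quantize(Decimal(1).scaleb(exponent), rounding=ROUND_HALF_UP))


def round_dp(x: float, places: int) -> float:
    """Half-up rounding to ``places`` decimal places."""
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-places),
                                           rounding=ROUND_HALF_UP))


def dose_report(ctdi_vol: float, scan_length: float, k: float) -> dict:
    """Raw and reported dose quantities for one protocol.

    Reported values follow radiology convention: DLP at 3 significant
    figures, effective dose at 2 decimal places.
    """
    raw_dlp = dlp(ctdi_vol, scan_length)
    reported_dlp = round_sig(raw_dlp, 3)
    raw_e = effective_dose(reported_dlp, k)
    return {
        "ctdi_vol_mGy": ctdi_vol,
        "scan_length_cm": scan_length,
        "k_mSv_per_mGycm": k,
        "dlp_mGycm_raw": raw_dlp,
        "dlp_mGycm": reported_dlp,
        "effective_dose_mSv_raw": raw_e,
        "effective_dose_mSv": round_dp(raw_e, 2),
    }
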