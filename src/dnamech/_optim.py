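"""Shared helpers around lmfit/MINPACK return codes."""


def fit_converged(result) -> bool:
    """True when a leastsq/lmfit result represents a usable minimum.

    MINPACK reports ier 6-8 ("ftol/xtol/gtol too small") when the
    requested tolerance is below what the problem can deliver; the
    iterate is still the best attainable minimum, so these are treated
    as convergence.  Only maxfev exhaustion (ier 5) and bad-input codes
    count as failure.
    """
    if result.success:
        return True
    ier = getattr(result, "ier", None)
    return ier in (1, 2, 3, 4, 6, 7, 8)
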