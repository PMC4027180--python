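"""Small protein sequence/composition utilities."""

from __future__ import annotations

# Molar absorption increments at 280 nm (M^-1 cm^-1), Pace et al. convention:
# Trp 5500, Tyr 1490, cystine (disulfide-bonded Cys pair) 125.
EPS_TRP = 5500
EPS_TYR = 1490
EPS_CYSTINE = 125


def extinction_coeff_280(n_trp: int, n_tyr: int, n_cystine: int = 0) -> int:
    """Theoretical molar extinction coefficient at 280 nm.

    Parameters
    ----------
    n_trp, n_tyr : int
        Number of tryptophan and tyrosine residues.
    n_cystine : int
        Number of disulfide bridges (cystines), not free cysteines.

    Returns
    -------
    int
        epsilon_280 in M^-1 cm^-1.
    """
    if min(n_trp, n_tyr, n_cystine) < 0:
        raise ValueError("residue counts must be non-negative")
    return EPS_TRP * n_trp + EPS_TYR * n_tyr + EPS_CYSTINE * n_cystine
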