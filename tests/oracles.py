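"""Independent term-by-term oracle for the reduced-model mass balances.

Deliberately written as literal transcriptions of each balance
(Accumulation = Inflow - Outflow + Reaction), separate from the production
code path, so that the two implementations can arbitrate each other.
"""

import numpy as np


def oracle_rates(x, p):
    """Five Monod reaction rates, each fraction spelled out."""
    X_COD, S_O, S_NH, S_NO, X_BH, X_BA = x
    aerobic_growth = (p.mu_h
                      * (X_COD / (p.K_COD + X_COD))
                      * (S_O / (p.K_OH + S_O))
                      * X_BH)
    anoxic_growth = (p.mu_h * p.eta_NOg
                     * (X_COD / (p.K_COD + X_COD))
                     * (S_NO / (p.K_NO + S_NO))
                     * (p.K_OH / (p.K_OH + S_O))
                     * X_BH)
    autotroph_growth = (p.mu_a
                        * (S_NH / (p.K_NHA + S_NH))
                        * (S_O / (p.K_OA + S_O))
                        * X_BA)
    return np.array([aerobic_growth, anoxic_growth, autotroph_growth,
                     p.b_h * X_BH, p.b_a * X_BA])


def oracle_rhs(x, influent, u, p):
    """Six mass balances assembled independently of aerompc.model."""
    X_COD, S_O, S_NH, S_NO, X_BH, X_BA = x
    g_aer, g_anx, g_aut, dec_h, dec_a = oracle_rates(x, p)
    dil = influent.Qin / p.V_o
    retention = p.f_w * (1.0 + p.f_r) / (p.f_r + p.f_w)

    d_cod = (- (1.0 / p.Yh) * (g_aer + g_anx)
             + (1.0 - p.f_p) * (dec_h + dec_a)
             + dil * (influent.XCOD_in - X_COD))
    d_so = ((p.Yh - 1.0) / p.Yh * g_aer
            + (p.Ya - 4.57) / p.Ya * g_aut
            - dil * S_O
            + u * (p.SO_sat - S_O))
    d_snh = (- p.i_xb * (g_aer + g_anx)
             - (p.i_xb + 1.0 / p.Ya) * g_aut
             + (p.i_xb - p.f_p * p.i_xp) * (dec_h + dec_a)
             + dil * (influent.SNH_in - S_NH))
    d_sno = (- (1.0 - p.Yh) / (2.86 * p.Yh) * g_anx
             + (1.0 / p.Ya) * g_aut
             - dil * S_NO)
    d_xbh = (g_aer + g_anx - dec_h
             + dil * (influent.XBH_in - retention * X_BH))
    d_xba = g_aut - dec_a - dil * retention * X_BA
    return np.array([d_cod, d_so, d_snh, d_sno, d_xbh, d_xba])
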