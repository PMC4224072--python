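"""Compiled ODE core coupling drug PK, bile acid disposition, ATP and injury.

One state vector carries the whole within-individual model:

* 25 bile acid amounts (5 species x 5 compartments, µmol),
* 5 delayed liver-intracellular concentrations (µM),
* hepatic ATP (mM), viable hepatocyte fraction, serum ALT fold, serum
  bilirubin fold,
* three bookkeeping integrals (cumulative fecal loss, LCA hydroxylation and
  synthesis, µmol) used by the mole-conservation audit,
* and, when a drug is dosed, the PK block (gut, portal, liver EC/IC,
  central, peripheral, induction multiplier, metabolite liver/central pools
  and elimination sinks) co-integrated in the same system.

Co-integrating PK keeps the right-hand side smooth between events, so the
stiff solver takes steps set by the dynamics rather than by an input grid;
dose administrations and meal-triggered gallbladder emptying are exact state
jumps between integration segments. BSEP, basolateral and ETC inhibition
read the liver intracellular drug concentration; NTCP inhibition reads
plasma. The right-hand side and its analytic Jacobian are numba-compiled
because population scenarios integrate the system tens of thousands of
times.

A legacy input path (:class:`DrugExposure`) accepts externally tabulated
drug concentration curves; it is used for flux-level analyses at constant
inhibitor concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .bile_acid import (
    BileAcidState,
    N_COMPARTMENTS,
    N_SPECIES,
    TransporterParams,
)

# base state layout
IDX_AMOUNT = 0
IDX_DELAY = 25
IDX_ATP = 30
IDX_VIABLE = 31
IDX_ALT = 32
IDX_BILI = 33
IDX_FECAL = 34
IDX_HYDROX = 35
IDX_SYNTH = 36
NSTATE_BASE = 37

# PK block offsets relative to IDX_PK == NSTATE_BASE (present when dosing)
IDX_PK = NSTATE_BASE
PK_GUT = 0
PK_PORTAL = 1
PK_LE = 2
PK_LIC = 3
PK_CENTRAL = 4
PK_PERIPH = 5
PK_IND = 6
PK_MET = 7  # then 2 states per metabolite, then sinks


def pk_block_size(n_met: int) -> int:
    return 10 + 4 * n_met


# parameter layout
_P_FIXED = 64
_P_STRIDE = 8
_MAX_CHEM = 3  # parent + up to 2 metabolites
_P_PK = _P_FIXED + _MAX_CHEM * _P_STRIDE  # 88
_P_MET = _P_PK + 18  # 106, 6 slots per metabolite
_P_LEN = _P_MET + 12  # 118

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9


@njit(cache=True)
def rhs(t, y, p, tgrid, liver_c, plasma_c):  # pragma: no cover - exercised via solver
    n = y.shape[0]
    dy = np.zeros(n)
    pk_on = p[61] > 0.0
    nm = int(p[62])
    v_liver = p[37]

    # ---- PK block ---------------------------------------------------------
    il = np.zeros(_MAX_CHEM)
    ip = np.zeros(_MAX_CHEM)
    if pk_on:
        b = IDX_PK
        G = y[b + PK_GUT]
        PORT = y[b + PK_PORTAL]
        LE = y[b + PK_LE]
        LIC = y[b + PK_LIC]
        CEN = y[b + PK_CENTRAL]
        PER = y[b + PK_PERIPH]
        E = y[b + PK_IND]
        ka = p[_P_PK]
        f_abs = p[_P_PK + 1]
        up_vmax = p[_P_PK + 2]
        up_km = p[_P_PK + 3]
        pas = p[_P_PK + 4]
        bil = p[_P_PK + 5]
        ren = p[_P_PK + 6]
        qp = p[_P_PK + 7]
        v_le = p[_P_PK + 8]
        v_lic = p[_P_PK + 9]
        v_c = p[_P_PK + 10]
        v_per = p[_P_PK + 11]
        k_ind = p[_P_PK + 12]
        fold_max = p[_P_PK + 13]
        ind_up = p[_P_PK + 14] > 0.0
        ind_met = p[_P_PK + 15] > 0.0
        q_pv = p[_P_PK + 16]
        q_ha = p[_P_PK + 17]
        q_h = q_pv + q_ha

        cP = PORT / p[38]
        cLE = LE / v_le
        cLIC = LIC / v_lic
        cC = CEN / v_c
        cPER = PER / v_per
        e_up = E if ind_up else 1.0
        e_met = E if ind_met else 1.0
        absorbed = ka * G
        uptake = e_up * up_vmax * cLE / (up_km + cLE) if up_vmax > 0.0 else 0.0
        passive = pas * (cLE - cLIC)
        met_tot = 0.0
        for j in range(nm):
            met_tot += e_met * p[_P_MET + 6 * j] * cLIC / (p[_P_MET + 6 * j + 1] + cLIC)
        dy[b + PK_GUT] = -absorbed
        dy[b + PK_PORTAL] = f_abs * absorbed + q_pv * cC - q_pv * cP
        dy[b + PK_LE] = q_pv * cP + q_ha * cC - q_h * cLE - uptake - passive
        dy[b + PK_LIC] = uptake + passive - met_tot - bil * cLIC
        dy[b + PK_CENTRAL] = q_h * cLE - q_h * cC - ren * cC - qp * (cC - cPER)
        dy[b + PK_PERIPH] = qp * (cC - cPER)
        dy[b + PK_IND] = k_ind * (fold_max - E)
        sink0 = b + PK_MET + 2 * nm
        dy[sink0] = (1.0 - f_abs) * absorbed
        dy[sink0 + 1] = bil * cLIC
        dy[sink0 + 2] = ren * cC
        for j in range(nm):
            vf = p[_P_MET + 6 * j]
            kf = p[_P_MET + 6 * j + 1]
            bilm = p[_P_MET + 6 * j + 2]
            effm = p[_P_MET + 6 * j + 3]
            renm = p[_P_MET + 6 * j + 4]
            vcm = p[_P_MET + 6 * j + 5]
            Ml = y[b + PK_MET + 2 * j]
            Mc = y[b + PK_MET + 2 * j + 1]
            cMl = Ml / v_liver
            cMc = Mc / vcm
            form = e_met * vf * cLIC / (kf + cLIC)
            exch = effm * (cMl - cMc)
            dy[b + PK_MET + 2 * j] = form - bilm * cMl - exch
            dy[b + PK_MET + 2 * j + 1] = exch - renm * cMc
            dy[sink0 + 3 + 2 * j] = bilm * cMl
            dy[sink0 + 3 + 2 * j + 1] = renm * cMc
        il[0] = cLIC if cLIC > 0.0 else 0.0
        ip[0] = cC if cC > 0.0 else 0.0
        for j in range(nm):
            cMl = y[b + PK_MET + 2 * j] / v_liver
            cMc = y[b + PK_MET + 2 * j + 1] / p[_P_MET + 6 * j + 5]
            il[1 + j] = cMl if cMl > 0.0 else 0.0
            ip[1 + j] = cMc if cMc > 0.0 else 0.0

    # ---- inhibition factors ----------------------------------------------
    f_bsep_c = 1.0
    f_bsep_n = 1.0
    f_ntcp_c = 1.0
    f_ntcp_n = 1.0
    f_baso_c = 1.0
    f_baso_n = 1.0
    etc_f = 1.0
    n_chem = int(p[59])
    for j in range(n_chem):
        base = _P_FIXED + _P_STRIDE * j
        if pk_on:
            cl = il[j]
            cp_ = ip[j]
        else:
            cl = np.interp(t, tgrid, liver_c[j])
            cp_ = np.interp(t, tgrid, plasma_c[j])
        ki = p[base + 0]
        mode = p[base + 1]
        if ki > 0.0:
            f = 1.0 + cl / ki
            if mode == 1.0:
                f_bsep_c *= f
            elif mode == 2.0:
                f_bsep_n *= f
        ki = p[base + 2]
        mode = p[base + 3]
        if ki > 0.0:
            f = 1.0 + cp_ / ki
            if mode == 1.0:
                f_ntcp_c *= f
            elif mode == 2.0:
                f_ntcp_n *= f
        ki = p[base + 4]
        mode = p[base + 5]
        if ki > 0.0:
            f = 1.0 + cl / ki
            if mode == 1.0:
                f_baso_c *= f
            elif mode == 2.0:
                f_baso_n *= f
        ki = p[base + 6]
        if ki > 0.0:
            etc_f *= 1.0 / (1.0 + cl / ki)

    # ---- bile acid fluxes -------------------------------------------------
    v_portal = p[38]
    v_systemic = p[39]
    q_portal = p[40]
    kconj = p[31]
    ksulf = p[32]
    kconv = p[33]
    kgut = p[34]
    floss = p[35]
    clhyd = p[36]

    for s in range(N_SPECIES):
        a_liv = y[5 * s + 0]
        a_gut = y[5 * s + 2]
        a_por = y[5 * s + 3]
        a_sys = y[5 * s + 4]
        cliv = a_liv / v_liver if a_liv > 0.0 else 0.0
        cpor = a_por / v_portal if a_por > 0.0 else 0.0
        csys = a_sys / v_systemic if a_sys > 0.0 else 0.0

        # canalicular export (BSEP): liver -> gallbladder
        jb = (p[0 + s] / f_bsep_n) * cliv / (p[5 + s] * f_bsep_c + cliv)
        # sinusoidal uptake (NTCP): portal -> liver
        jn = (p[10 + s] / f_ntcp_n) * cpor / (p[15 + s] * f_ntcp_c + cpor)
        # basolateral efflux (MRP3/4-like): liver -> systemic
        jba = (p[20 + s] / f_baso_n) * cliv / (p[25 + s] * f_baso_c + cliv)
        # gut transit: fecal share lost, remainder reabsorbed to portal blood;
        # LCA-class species are poorly reabsorbed (larger fecal share)
        f_s = floss if s < 2 else p[60]
        jout = kgut * a_gut
        jfec = f_s * jout
        jpor = (1.0 - f_s) * jout
        # splanchnic blood exchange
        jspill = q_portal * cpor
        jret = q_portal * csys

        dy[5 * s + 0] += jn - jb - jba
        dy[5 * s + 1] += jb
        dy[5 * s + 2] += -jout
        dy[5 * s + 3] += jpor + jret - jn - jspill
        dy[5 * s + 4] += jba + jspill - jret
        dy[IDX_FECAL] += jfec

        # rat-only LCA detoxification (hydroxylation), LCA-class in liver
        if s >= 2 and clhyd > 0.0:
            jh = clhyd * cliv
            dy[5 * s + 0] -= jh
            dy[IDX_HYDROX] += jh

        # delayed liver concentration driving toxicity
        tau = p[44] if s < 2 else p[48]
        dy[IDX_DELAY + s] = tau * (cliv - y[IDX_DELAY + s])

    # hepatic synthesis (CDCA only) and conjugation chemistry
    synth = p[30]
    dy[0] += synth
    dy[IDX_SYNTH] += synth
    jconj_c = kconj * y[0]
    jconj_l = kconj * y[10]
    jsulf = ksulf * y[10]
    dy[0] -= jconj_c
    dy[5] += jconj_c
    dy[10] -= jconj_l + jsulf
    dy[15] += jconj_l
    dy[20] += jsulf
    # gut flora conversion: CDCA-class -> corresponding LCA-class
    jcv0 = kconv * y[2]
    jcv1 = kconv * y[7]
    dy[2] -= jcv0
    dy[12] += jcv0
    dy[7] -= jcv1
    dy[17] += jcv1

    # ---- toxicity signal and ATP -----------------------------------------
    cd_cdca = y[IDX_DELAY + 0] + y[IDX_DELAY + 1]
    cd_lca = y[IDX_DELAY + 2] + y[IDX_DELAY + 3] + y[IDX_DELAY + 4]
    s_tot = 1.0
    if cd_cdca > 0.0:
        ch = cd_cdca ** p[43]
        s_tot *= 1.0 / (1.0 + p[41] * ch / (p[42] ** p[43] + ch))
    if cd_lca > 0.0:
        ch = cd_lca ** p[47]
        s_tot *= 1.0 / (1.0 + p[45] * ch / (p[46] ** p[47] + ch))

    atp = y[IDX_ATP]
    baseline = p[51]
    dy[IDX_ATP] = p[49] * s_tot * etc_f - p[50] * atp / baseline

    # ---- necrosis, regeneration, serum biomarkers ------------------------
    thr = p[52]
    viable = y[IDX_VIABLE]
    deficit = (thr - atp) / thr
    if deficit < 0.0:
        deficit = 0.0
    hazard = p[53] * deficit ** p[54]
    necrosis = hazard * viable
    dy[IDX_VIABLE] = -necrosis + p[58] * (1.0 - viable)
    dy[IDX_ALT] = p[55] * necrosis - p[56] * (y[IDX_ALT] - 1.0)
    vf = viable if viable > 1e-6 else 1e-6
    dy[IDX_BILI] = p[57] * (1.0 / vf - y[IDX_BILI])
    return dy


@njit(cache=True)
def jac(t, y, p, tgrid, liver_c, plasma_c):  # pragma: no cover - exercised via solver
    """Analytic Jacobian of :func:`rhs` (needed by the stiff solver)."""
    n = y.shape[0]
    J = np.zeros((n, n))
    pk_on = p[61] > 0.0
    nm = int(p[62])
    v_liver = p[37]

    # drug concentrations and the state index + volume they derive from
    il = np.zeros(_MAX_CHEM)
    ip = np.zeros(_MAX_CHEM)
    il_idx = np.full(_MAX_CHEM, -1)
    ip_idx = np.full(_MAX_CHEM, -1)
    il_vol = np.ones(_MAX_CHEM)
    ip_vol = np.ones(_MAX_CHEM)
    if pk_on:
        b = IDX_PK
        v_lic = p[_P_PK + 9]
        v_c = p[_P_PK + 10]
        il[0] = max(y[b + PK_LIC] / v_lic, 0.0)
        ip[0] = max(y[b + PK_CENTRAL] / v_c, 0.0)
        il_idx[0] = b + PK_LIC
        ip_idx[0] = b + PK_CENTRAL
        il_vol[0] = v_lic
        ip_vol[0] = v_c
        for j in range(nm):
            vcm = p[_P_MET + 6 * j + 5]
            il[1 + j] = max(y[b + PK_MET + 2 * j] / v_liver, 0.0)
            ip[1 + j] = max(y[b + PK_MET + 2 * j + 1] / vcm, 0.0)
            il_idx[1 + j] = b + PK_MET + 2 * j
            ip_idx[1 + j] = b + PK_MET + 2 * j + 1
            il_vol[1 + j] = v_liver
            ip_vol[1 + j] = vcm

    f_bsep_c = 1.0
    f_bsep_n = 1.0
    f_ntcp_c = 1.0
    f_ntcp_n = 1.0
    f_baso_c = 1.0
    f_baso_n = 1.0
    etc_f = 1.0
    n_chem = int(p[59])
    for j in range(n_chem):
        base = _P_FIXED + _P_STRIDE * j
        if pk_on:
            cl = il[j]
            cp_ = ip[j]
        else:
            cl = np.interp(t, tgrid, liver_c[j])
            cp_ = np.interp(t, tgrid, plasma_c[j])
        ki = p[base + 0]
        mode = p[base + 1]
        if ki > 0.0:
            f = 1.0 + cl / ki
            if mode == 1.0:
                f_bsep_c *= f
            elif mode == 2.0:
                f_bsep_n *= f
        ki = p[base + 2]
        mode = p[base + 3]
        if ki > 0.0:
            f = 1.0 + cp_ / ki
            if mode == 1.0:
                f_ntcp_c *= f
            elif mode == 2.0:
                f_ntcp_n *= f
        ki = p[base + 4]
        mode = p[base + 5]
        if ki > 0.0:
            f = 1.0 + cl / ki
            if mode == 1.0:
                f_baso_c *= f
            elif mode == 2.0:
                f_baso_n *= f
        ki = p[base + 6]
        if ki > 0.0:
            etc_f *= 1.0 / (1.0 + cl / ki)

    v_portal = p[38]
    v_systemic = p[39]
    q_portal = p[40]
    kconj = p[31]
    ksulf = p[32]
    kconv = p[33]
    kgut = p[34]
    floss = p[35]
    clhyd = p[36]

    for s in range(N_SPECIES):
        L = 5 * s + 0
        G = 5 * s + 2
        P = 5 * s + 3
        S = 5 * s + 4
        GB = 5 * s + 1
        a_liv = y[L] if y[L] > 0.0 else 0.0
        a_por = y[P] if y[P] > 0.0 else 0.0
        cliv = a_liv / v_liver
        cpor = a_por / v_portal
        vb = p[0 + s] / f_bsep_n
        kb = p[5 + s] * f_bsep_c
        vn = p[10 + s] / f_ntcp_n
        kn = p[15 + s] * f_ntcp_c
        vba = p[20 + s] / f_baso_n
        kba = p[25 + s] * f_baso_c
        jb = vb * cliv / (kb + cliv)
        jn = vn * cpor / (kn + cpor)
        jba = vba * cliv / (kba + cliv)
        djb = vb * kb / ((kb + cliv) * (kb + cliv)) / v_liver
        djn = vn * kn / ((kn + cpor) * (kn + cpor)) / v_portal
        djba = vba * kba / ((kba + cliv) * (kba + cliv)) / v_liver
        f_s = floss if s < 2 else p[60]

        J[L, L] += -(djb + djba)
        J[L, P] += djn
        J[GB, L] += djb
        J[G, G] += -kgut
        J[P, G] += (1.0 - f_s) * kgut
        J[P, P] += -djn - q_portal / v_portal
        J[P, S] += q_portal / v_systemic
        J[S, L] += djba
        J[S, P] += q_portal / v_portal
        J[S, S] += -q_portal / v_systemic
        J[IDX_FECAL, G] += f_s * kgut
        if s >= 2 and clhyd > 0.0:
            J[L, L] += -clhyd / v_liver
            J[IDX_HYDROX, L] += clhyd / v_liver

        tau = p[44] if s < 2 else p[48]
        J[IDX_DELAY + s, L] += tau / v_liver
        J[IDX_DELAY + s, IDX_DELAY + s] += -tau

        # cross-terms: transporter fluxes vs drug states
        if pk_on:
            for j in range(n_chem):
                base = _P_FIXED + _P_STRIDE * j
                # BSEP (liver drug conc)
                ki = p[base + 0]
                mode = p[base + 1]
                if ki > 0.0 and il_idx[j] >= 0:
                    if mode == 2.0:  # noncompetitive: d jb / d Il = -jb/(ki+Il)
                        d = -jb / (ki + il[j]) / il_vol[j]
                    else:  # competitive: Km scales with f_c
                        d = (
                            -jb * kb / ((kb + cliv) * (ki + il[j])) / il_vol[j]
                            if cliv > 0.0
                            else 0.0
                        )
                    J[L, il_idx[j]] += -d
                    J[GB, il_idx[j]] += d
                # NTCP (plasma drug conc)
                ki = p[base + 2]
                mode = p[base + 3]
                if ki > 0.0 and ip_idx[j] >= 0:
                    if mode == 2.0:
                        d = -jn / (ki + ip[j]) / ip_vol[j]
                    else:
                        d = (
                            -jn * kn / ((kn + cpor) * (ki + ip[j])) / ip_vol[j]
                            if cpor > 0.0
                            else 0.0
                        )
                    J[L, ip_idx[j]] += d
                    J[P, ip_idx[j]] += -d
                # basolateral (liver drug conc)
                ki = p[base + 4]
                mode = p[base + 5]
                if ki > 0.0 and il_idx[j] >= 0:
                    if mode == 2.0:
                        d = -jba / (ki + il[j]) / il_vol[j]
                    else:
                        d = (
                            -jba * kba / ((kba + cliv) * (ki + il[j])) / il_vol[j]
                            if cliv > 0.0
                            else 0.0
                        )
                    J[L, il_idx[j]] += -d
                    J[S, il_idx[j]] += d

    J[0, 0] += -kconj
    J[5, 0] += kconj
    J[10, 10] += -(kconj + ksulf)
    J[15, 10] += kconj
    J[20, 10] += ksulf
    J[2, 2] += -kconv
    J[12, 2] += kconv
    J[7, 7] += -kconv
    J[17, 7] += kconv

    # ATP row
    cd_cdca = y[IDX_DELAY + 0] + y[IDX_DELAY + 1]
    cd_lca = y[IDX_DELAY + 2] + y[IDX_DELAY + 3] + y[IDX_DELAY + 4]
    s1 = 1.0
    ds1 = 0.0
    if cd_cdca > 0.0:
        ch = cd_cdca ** p[43]
        den = p[42] ** p[43] + ch
        g = p[41] * ch / den
        s1 = 1.0 / (1.0 + g)
        dg = p[41] * p[43] * cd_cdca ** (p[43] - 1.0) * p[42] ** p[43] / (den * den)
        ds1 = -dg * s1 * s1
    s2 = 1.0
    ds2 = 0.0
    if cd_lca > 0.0:
        ch = cd_lca ** p[47]
        den = p[46] ** p[47] + ch
        g = p[45] * ch / den
        s2 = 1.0 / (1.0 + g)
        dg = p[45] * p[47] * cd_lca ** (p[47] - 1.0) * p[46] ** p[47] / (den * den)
        ds2 = -dg * s2 * s2
    kse = p[49] * etc_f
    J[IDX_ATP, IDX_DELAY + 0] = kse * ds1 * s2
    J[IDX_ATP, IDX_DELAY + 1] = kse * ds1 * s2
    J[IDX_ATP, IDX_DELAY + 2] = kse * s1 * ds2
    J[IDX_ATP, IDX_DELAY + 3] = kse * s1 * ds2
    J[IDX_ATP, IDX_DELAY + 4] = kse * s1 * ds2
    J[IDX_ATP, IDX_ATP] = -p[50] / p[51]
    # ETC inhibitors couple ATP to the drug liver states
    if pk_on:
        for j in range(n_chem):
            ki = p[_P_FIXED + _P_STRIDE * j + 6]
            if ki > 0.0 and il_idx[j] >= 0:
                J[IDX_ATP, il_idx[j]] += (
                    -p[49] * s1 * s2 * etc_f / (ki + il[j]) / il_vol[j]
                )

    # injury rows
    thr = p[52]
    atp = y[IDX_ATP]
    viable = y[IDX_VIABLE]
    deficit = (thr - atp) / thr
    if deficit < 0.0:
        deficit = 0.0
    hazard = p[53] * deficit ** p[54]
    dhaz_datp = 0.0
    if deficit > 0.0:
        dhaz_datp = -p[53] * p[54] * deficit ** (p[54] - 1.0) / thr
    J[IDX_VIABLE, IDX_VIABLE] = -hazard - p[58]
    J[IDX_VIABLE, IDX_ATP] = -dhaz_datp * viable
    J[IDX_ALT, IDX_VIABLE] = p[55] * hazard
    J[IDX_ALT, IDX_ATP] = p[55] * viable * dhaz_datp
    J[IDX_ALT, IDX_ALT] = -p[56]
    vf = viable if viable > 1e-6 else 1e-6
    J[IDX_BILI, IDX_VIABLE] = -p[57] / (vf * vf) if viable > 1e-6 else 0.0
    J[IDX_BILI, IDX_BILI] = -p[57]

    # ---- PK block Jacobian ------------------------------------------------
    if pk_on:
        b = IDX_PK
        ka = p[_P_PK]
        f_abs = p[_P_PK + 1]
        up_vmax = p[_P_PK + 2]
        up_km = p[_P_PK + 3]
        pas = p[_P_PK + 4]
        bil = p[_P_PK + 5]
        ren = p[_P_PK + 6]
        qp = p[_P_PK + 7]
        v_le = p[_P_PK + 8]
        v_lic = p[_P_PK + 9]
        v_c = p[_P_PK + 10]
        v_per = p[_P_PK + 11]
        k_ind = p[_P_PK + 12]
        ind_up = p[_P_PK + 14] > 0.0
        ind_met = p[_P_PK + 15] > 0.0
        q_pv = p[_P_PK + 16]
        q_ha = p[_P_PK + 17]
        q_h = q_pv + q_ha
        E = y[b + PK_IND]
        cLE = y[b + PK_LE] / v_le
        cLIC = y[b + PK_LIC] / v_lic
        e_up = E if ind_up else 1.0
        e_met = E if ind_met else 1.0
        dupt_dLE = e_up * up_vmax * up_km / ((up_km + cLE) * (up_km + cLE)) / v_le
        upt = e_up * up_vmax * cLE / (up_km + cLE) if up_vmax > 0.0 else 0.0
        dupt_dE = (up_vmax * cLE / (up_km + cLE)) if (ind_up and up_vmax > 0.0) else 0.0
        dmet_dLIC = 0.0
        dmet_dE = 0.0
        for j in range(nm):
            vf_ = p[_P_MET + 6 * j]
            kf = p[_P_MET + 6 * j + 1]
            dmet_dLIC += e_met * vf_ * kf / ((kf + cLIC) * (kf + cLIC)) / v_lic
            if ind_met:
                dmet_dE += vf_ * cLIC / (kf + cLIC)

        J[b + PK_GUT, b + PK_GUT] = -ka
        J[b + PK_PORTAL, b + PK_GUT] = f_abs * ka
        J[b + PK_PORTAL, b + PK_CENTRAL] = q_pv / v_c
        J[b + PK_PORTAL, b + PK_PORTAL] = -q_pv / p[38]
        J[b + PK_LE, b + PK_PORTAL] = q_pv / p[38]
        J[b + PK_LE, b + PK_CENTRAL] = q_ha / v_c
        J[b + PK_LE, b + PK_LE] = -(q_h / v_le) - dupt_dLE - pas / v_le
        J[b + PK_LE, b + PK_LIC] = pas / v_lic
        J[b + PK_LE, b + PK_IND] = -dupt_dE
        J[b + PK_LIC, b + PK_LE] = dupt_dLE + pas / v_le
        J[b + PK_LIC, b + PK_LIC] = -pas / v_lic - dmet_dLIC - bil / v_lic
        J[b + PK_LIC, b + PK_IND] = dupt_dE - dmet_dE
        J[b + PK_CENTRAL, b + PK_LE] = q_h / v_le
        J[b + PK_CENTRAL, b + PK_CENTRAL] = -(q_h + ren + qp) / v_c
        J[b + PK_CENTRAL, b + PK_PERIPH] = qp / v_per
        J[b + PK_PERIPH, b + PK_CENTRAL] = qp / v_c
        J[b + PK_PERIPH, b + PK_PERIPH] = -qp / v_per
        J[b + PK_IND, b + PK_IND] = -k_ind
        sink0 = b + PK_MET + 2 * nm
        J[sink0, b + PK_GUT] = (1.0 - f_abs) * ka
        J[sink0 + 1, b + PK_LIC] = bil / v_lic
        J[sink0 + 2, b + PK_CENTRAL] = ren / v_c
        for j in range(nm):
            vf_ = p[_P_MET + 6 * j]
            kf = p[_P_MET + 6 * j + 1]
            bilm = p[_P_MET + 6 * j + 2]
            effm = p[_P_MET + 6 * j + 3]
            renm = p[_P_MET + 6 * j + 4]
            vcm = p[_P_MET + 6 * j + 5]
            dform_dLIC = e_met * vf_ * kf / ((kf + cLIC) * (kf + cLIC)) / v_lic
            ML = b + PK_MET + 2 * j
            MC = b + PK_MET + 2 * j + 1
            J[ML, b + PK_LIC] = dform_dLIC
            if ind_met:
                J[ML, b + PK_IND] = vf_ * cLIC / (kf + cLIC)
            J[ML, ML] = -(bilm + effm) / v_liver
            J[ML, MC] = effm / vcm
            J[MC, ML] = effm / v_liver
            J[MC, MC] = -(effm + renm) / vcm
            J[sink0 + 3 + 2 * j, ML] = bilm / v_liver
            J[sink0 + 3 + 2 * j + 1, MC] = renm / vcm
    return J


# -- parameter packing -----------------------------------------------------

def _inhibition_slots(specs) -> np.ndarray:
    slot = np.zeros(_P_STRIDE)
    offsets = {"BSEP": 0, "NTCP": 2, "BASOLATERAL": 4}
    for spec in specs:
        if spec.transporter == "ETC":
            slot[6] = spec.ki_um
            continue
        o = offsets[spec.transporter]
        slot[o] = spec.ki_um
        slot[o + 1] = 1.0 if spec.mode == "competitive" else 2.0
    return slot


def pack_params(
    transporters: TransporterParams,
    physiology,
    tox=None,
    injury=None,
    inhibitors=(),
    compound=None,
) -> np.ndarray:
    """Flatten all model parameters into the kernel's parameter vector.

    ``inhibitors`` (legacy path) is one InhibitionSpec list per tabulated
    chemical species; when ``compound`` is given the inhibition lists and PK
    parameters are taken from it instead and the PK block is activated.
    """
    from .hepatotox import default_injury_params, default_tox_params
    from .pbpk import LIVER_EC_FRACTION

    tox = tox or default_tox_params(physiology)
    injury = injury or default_injury_params(physiology)
    if compound is not None:
        inhibitors = [compound.inhibitions] + [
            m.product_inhibitions for m in compound.metabolites
        ]
    n_chem = len(inhibitors)
    if n_chem > _MAX_CHEM:
        raise ValueError(f"at most {_MAX_CHEM} chemical species supported")
    p = np.zeros(_P_LEN)
    p[0:5] = transporters.vmax_umol_per_h["BSEP"]
    p[5:10] = transporters.km_um["BSEP"]
    p[10:15] = transporters.vmax_umol_per_h["NTCP"]
    p[15:20] = transporters.km_um["NTCP"]
    p[20:25] = transporters.vmax_umol_per_h["BASOLATERAL"]
    p[25:30] = transporters.km_um["BASOLATERAL"]
    p[30] = physiology.ba_synthesis_rate_umol_per_h
    p[31] = physiology.conjugation_k_per_h
    p[32] = physiology.sulfation_k_per_h
    p[33] = physiology.gut_conversion_k_per_h
    p[34] = physiology.gut_transit_k_per_h
    p[35] = physiology.fecal_loss_fraction
    p[36] = physiology.lca_hydroxylation_cl_l_per_h
    p[37] = physiology.liver_volume_l
    p[38] = physiology.portal_volume_l
    p[39] = physiology.blood_volume_l
    p[40] = physiology.q_portal_l_per_h
    for i, cls in enumerate(("CDCA", "LCA")):
        cp = tox.classes[cls]
        p[41 + 4 * i] = cp.vmax_s
        p[42 + 4 * i] = cp.km_s_um
        p[43 + 4 * i] = cp.hill
        p[44 + 4 * i] = cp.tau_per_h
    p[49] = tox.k_synth_mm_per_h
    p[50] = tox.k_usage_mm_per_h
    p[51] = tox.baseline_atp_mm
    p[52] = injury.atp_death_threshold_mm
    p[53] = injury.k_necrosis_max_per_h
    p[54] = injury.necrosis_hill
    p[55] = injury.alt_release_fold_per_fraction
    p[56] = injury.k_alt_clear_per_h
    p[57] = injury.k_bili_clear_per_h
    p[58] = injury.k_regen_per_h
    p[59] = n_chem
    p[60] = physiology.lca_fecal_loss_fraction
    for j, specs in enumerate(inhibitors):
        p[_P_FIXED + _P_STRIDE * j : _P_FIXED + _P_STRIDE * (j + 1)] = (
            _inhibition_slots(specs)
        )
    if compound is not None:
        nm = len(compound.metabolites)
        if nm > _MAX_CHEM - 1:
            raise ValueError("at most 2 metabolites supported")
        kg075 = physiology.allometric_kg075
        p[61] = 1.0
        p[62] = nm
        p[_P_PK] = compound.ka_per_h
        p[_P_PK + 1] = compound.f_abs
        p[_P_PK + 2] = compound.uptake_vmax_umol_per_h_kg075 * kg075
        p[_P_PK + 3] = compound.uptake_km_um
        p[_P_PK + 4] = compound.passive_cl_l_per_h
        p[_P_PK + 5] = compound.biliary_cl_ml_per_h_kg075 * kg075 / 1000.0
        p[_P_PK + 6] = compound.renal_cl_l_per_h
        p[_P_PK + 7] = compound.q_peripheral_l_per_h
        p[_P_PK + 8] = LIVER_EC_FRACTION * physiology.liver_volume_l
        p[_P_PK + 9] = (1.0 - LIVER_EC_FRACTION) * physiology.liver_volume_l
        p[_P_PK + 10] = compound.v_central_l_per_kg * physiology.bodyweight_kg
        p[_P_PK + 11] = max(
            compound.v_peripheral_l_per_kg * physiology.bodyweight_kg, 1e-9
        )
        ind = compound.induction
        p[_P_PK + 12] = ind.k_ind_per_h if ind else 0.0
        p[_P_PK + 13] = ind.fold_max if ind else 1.0
        p[_P_PK + 14] = 1.0 if (ind and "uptake_vmax" in ind.targets) else 0.0
        p[_P_PK + 15] = 1.0 if (ind and "metabolism_vmax" in ind.targets) else 0.0
        p[_P_PK + 16] = physiology.q_portal_l_per_h
        p[_P_PK + 17] = physiology.q_hepatic_artery_l_per_h
        for j, m in enumerate(compound.metabolites):
            p[_P_MET + 6 * j] = m.vmax_formation_umol_per_h
            p[_P_MET + 6 * j + 1] = m.km_formation_um
            p[_P_MET + 6 * j + 2] = (
                m.product_biliary_cl_ml_per_h_kg075 * kg075 / 1000.0
            )
            p[_P_MET + 6 * j + 3] = m.product_efflux_cl_l_per_h
            p[_P_MET + 6 * j + 4] = m.product_renal_cl_l_per_h
            p[_P_MET + 6 * j + 5] = max(
                m.product_v_central_l_per_kg * physiology.bodyweight_kg, 1e-9
            )
    return p


def state_to_vector(
    state: BileAcidState | None, atp_mm: float, n_pk: int = 0
) -> np.ndarray:
    y = np.zeros(NSTATE_BASE + n_pk)
    if state is not None:
        y[IDX_AMOUNT : IDX_AMOUNT + 25] = state.amounts_umol.ravel()
        y[IDX_DELAY : IDX_DELAY + 5] = state.delayed_liver_conc_um
    y[IDX_ATP] = atp_mm
    y[IDX_VIABLE] = 1.0
    y[IDX_ALT] = 1.0
    y[IDX_BILI] = 1.0
    if n_pk:
        y[IDX_PK + PK_IND] = 1.0  # induction multiplier starts uninduced
    return y


def vector_to_state(y: np.ndarray) -> BileAcidState:
    return BileAcidState(
        np.clip(y[IDX_AMOUNT : IDX_AMOUNT + 25], 0.0, None).reshape(
            N_SPECIES, N_COMPARTMENTS
        ),
        y[IDX_DELAY : IDX_DELAY + 5].copy(),
    )


# -- legacy tabulated drug input -------------------------------------------

@dataclass
class DrugExposure:
    """Externally tabulated drug concentration inputs (flux-level analyses)."""

    tgrid_h: np.ndarray
    liver_conc_um: np.ndarray  # (n chemical species, n times)
    plasma_conc_um: np.ndarray
    inhibitions: list  # per chemical species: list of InhibitionSpec
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tgrid_h = np.ascontiguousarray(self.tgrid_h, dtype=float)
        self.liver_conc_um = np.ascontiguousarray(self.liver_conc_um, dtype=float)
        self.plasma_conc_um = np.ascontiguousarray(self.plasma_conc_um, dtype=float)
        if self.liver_conc_um.ndim != 2:
            raise ValueError("liver_conc_um must be 2-D (species, time)")
        if self.liver_conc_um.shape != self.plasma_conc_um.shape:
            raise ValueError("liver and plasma concentration shapes differ")
        if len(self.inhibitions) != self.liver_conc_um.shape[0]:
            raise ValueError("one inhibition list per chemical species required")


_EMPTY_T = np.array([0.0])
_EMPTY_C = np.zeros((0, 1))


# -- trace -----------------------------------------------------------------

@dataclass
class ExposureTrace:
    """Sampled trajectory of one individual simulation."""

    times_h: np.ndarray
    states: np.ndarray  # (n times, n states)
    params: np.ndarray
    clip_events: int = 0
    administered_umol: np.ndarray | None = None
    drug_names: list = field(default_factory=list)

    @property
    def atp_mm(self) -> np.ndarray:
        return self.states[:, IDX_ATP]

    @property
    def viable_fraction(self) -> np.ndarray:
        return self.states[:, IDX_VIABLE]

    @property
    def alt_fold(self) -> np.ndarray:
        return self.states[:, IDX_ALT]

    @property
    def bili_fold(self) -> np.ndarray:
        return self.states[:, IDX_BILI]

    @property
    def n_metabolites(self) -> int:
        return int(self.params[62])

    @property
    def has_pk(self) -> bool:
        return self.params[61] > 0.0

    def liver_toxic_conc_um(self) -> np.ndarray:
        """Total liver intracellular toxic bile acid concentration (µM)."""
        v = self.params[37]
        liver = self.states[:, IDX_AMOUNT : IDX_AMOUNT + 25].reshape(
            -1, N_SPECIES, N_COMPARTMENTS
        )[:, :, 0]
        return liver.sum(axis=1) / v

    def liver_class_conc_um(self) -> dict:
        v = self.params[37]
        liver = self.states[:, IDX_AMOUNT : IDX_AMOUNT + 25].reshape(
            -1, N_SPECIES, N_COMPARTMENTS
        )[:, :, 0]
        return {
            "CDCA": liver[:, :2].sum(axis=1) / v,
            "LCA": liver[:, 2:].sum(axis=1) / v,
        }

    def systemic_conc_um(self) -> np.ndarray:
        v = self.params[39]
        sysb = self.states[:, IDX_AMOUNT : IDX_AMOUNT + 25].reshape(
            -1, N_SPECIES, N_COMPARTMENTS
        )[:, :, 4]
        return sysb.sum(axis=1) / v

    def drug_liver_conc_um(self, chem: int = 0) -> np.ndarray:
        if not self.has_pk:
            raise ValueError("trace carries no PK block")
        if chem == 0:
            return self.states[:, IDX_PK + PK_LIC] / self.params[_P_PK + 9]
        return self.states[:, IDX_PK + PK_MET + 2 * (chem - 1)] / self.params[37]

    def drug_plasma_conc_um(self, chem: int = 0) -> np.ndarray:
        if not self.has_pk:
            raise ValueError("trace carries no PK block")
        if chem == 0:
            return self.states[:, IDX_PK + PK_CENTRAL] / self.params[_P_PK + 10]
        return (
            self.states[:, IDX_PK + PK_MET + 2 * (chem - 1) + 1]
            / self.params[_P_MET + 6 * (chem - 1) + 5]
        )

    def final_state(self) -> BileAcidState:
        return vector_to_state(self.states[-1])

    def final_atp_mm(self) -> float:
        return float(self.states[-1, IDX_ATP])

    def min_atp_mm(self) -> float:
        return float(self.atp_mm.min())

    def peak_alt_fold(self) -> float:
        return float(self.alt_fold.max())

    def peak_bili_fold(self) -> float:
        return float(self.bili_fold.max())

    def peak_normalized_lft(self) -> float:
        return float(np.max(np.maximum(self.alt_fold / 5.0, self.bili_fold / 3.0)))

    def biomarkers(self):
        from .hepatotox import BiomarkerTrace

        return BiomarkerTrace(
            self.times_h,
            self.atp_mm,
            self.viable_fraction,
            self.alt_fold,
            self.bili_fold,
        )

    # -- audits ------------------------------------------------------------
    def mole_balance_error(self) -> float:
        """Max relative violation of d(total BA) = synthesis − fecal − hydroxylation."""
        total = self.states[:, IDX_AMOUNT : IDX_AMOUNT + 25].sum(axis=1)
        book = (
            self.states[:, IDX_SYNTH]
            - self.states[:, IDX_FECAL]
            - self.states[:, IDX_HYDROX]
        )
        expected = total[0] + (book - book[0])
        denom = np.maximum(np.abs(expected).max(), 1.0)
        return float(np.abs(total - expected).max() / denom)

    def drug_mass_balance_error(self) -> float:
        """Max relative |administered − (PK compartments + sinks)| over time."""
        if not self.has_pk or self.administered_umol is None:
            raise ValueError("trace carries no dosed PK block")
        pk = self.states[:, IDX_PK :]
        nm = self.n_metabolites
        # everything except the induction state is drug mass
        mass = pk.sum(axis=1) - pk[:, PK_IND]
        denom = np.maximum(self.administered_umol, 1e-12)
        return float(np.max(np.abs(self.administered_umol - mass) / denom))

    def daily_compartment_totals(self) -> np.ndarray:
        days = np.arange(0, int(self.times_h[-1] // 24) + 1) * 24.0
        idx = np.searchsorted(self.times_h, days)
        idx = np.clip(idx, 0, len(self.times_h) - 1)
        amts = self.states[idx, IDX_AMOUNT : IDX_AMOUNT + 25].reshape(
            len(idx), N_SPECIES, N_COMPARTMENTS
        )
        return amts.sum(axis=1)

    def is_periodic(self, tol: float = 0.005) -> bool:
        d = self.daily_compartment_totals()
        if len(d) < 3:
            return False
        prev, last = d[-2], d[-1]
        # compartments holding under 0.1% of the pool cannot block convergence
        denom = np.maximum(np.maximum(prev, last), 1e-3 * max(last.sum(), 1e-12))
        return bool(np.all(np.abs(last - prev) / denom < tol))


# -- integration driver ----------------------------------------------------

class IntegrationError(RuntimeError):
    pass


def simulate_exposure(
    transporters: TransporterParams,
    physiology,
    tox=None,
    injury=None,
    duration_h: float = 720.0,
    initial_state: BileAcidState | None = None,
    initial_atp_mm: float | None = None,
    compound=None,
    regimen=None,
    drug: DrugExposure | None = None,
    sample_dt_h: float = 1.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ExposureTrace:
    """Integrate one individual over ``duration_h`` with meal and dose events.

    Dosing is specified by ``compound`` + ``regimen`` (PK co-integrated); the
    drug-free system runs when both are None. ``drug`` accepts a tabulated
    concentration input instead (mutually exclusive with ``compound``).
    """
    from .bile_acid import COMPARTMENT_INDEX

    if compound is not None and drug is not None:
        raise ValueError("give either a compound+regimen or a tabulated exposure")
    if (compound is None) != (regimen is None):
        raise ValueError("compound and regimen must be given together")

    inhibitors = drug.inhibitions if drug is not None else []
    p = pack_params(
        transporters, physiology, tox, injury, inhibitors, compound=compound
    )
    if drug is not None:
        tgrid, liv, pla = drug.tgrid_h, drug.liver_conc_um, drug.plasma_conc_um
    else:
        tgrid, liv, pla = _EMPTY_T, _EMPTY_C, _EMPTY_C

    nm = len(compound.metabolites) if compound is not None else 0
    n_pk = pk_block_size(nm) if compound is not None else 0
    y = state_to_vector(
        initial_state,
        initial_atp_mm if initial_atp_mm is not None else physiology.baseline_atp_mm,
        n_pk=n_pk,
    )

    meal_times = physiology.meal_schedule(duration_h)
    dose_times = []
    dose_umol = 0.0
    if compound is not None:
        dose_times = [t for t in regimen.dose_times_h if t < duration_h]
        dose_umol = regimen.dose_umol(compound, physiology.bodyweight_kg)
    events = sorted(set([0.0] + meal_times + dose_times + [duration_h]))
    meal_set = set(meal_times)
    dose_set = set(dose_times)
    gb = COMPARTMENT_INDEX["gallbladder"]
    gut = COMPARTMENT_INDEX["gut_lumen"]
    frac = physiology.gallbladder_empty_fraction
    oral = compound is not None and regimen.route == "oral"

    given = 0.0
    all_t = [np.array([0.0])]
    all_y = [y.copy()[None, :]]
    administered = [0.0]
    clip_events = 0
    for t0, t1 in zip(events[:-1], events[1:]):
        if t0 in dose_set:
            tgt = IDX_PK + (PK_GUT if oral else PK_CENTRAL)
            y[tgt] += dose_umol
            given += dose_umol
            administered[-1] = given
            all_y[-1][-1] = y  # record the post-dose state at this time point
        if t1 <= t0:
            continue
        n_samp = max(int(np.ceil((t1 - t0) / sample_dt_h)), 1)
        t_eval = np.linspace(t0, t1, n_samp + 1)
        # odeint rather than solve_ivp(LSODA): same stiff core, but the f2py
        # wrapper releases its Fortran work arrays, which matters over the
        # ~10^5 event segments of a population study
        ys, info = odeint(
            rhs,
            y,
            t_eval,
            args=(p, tgrid, liv, pla),
            Dfun=jac,
            rtol=rtol,
            atol=atol,
            tfirst=True,
            mxstep=10000,
            full_output=True,
        )
        if info["message"] != "Integration successful.":
            worst = int(np.argmin(ys[-1]))
            raise IntegrationError(
                f"ODE integration failed in [{t0:.1f}, {t1:.1f}] h "
                f"(state index {worst}): {info['message']}"
            )
        y = ys[-1].copy()
        neg = y[: IDX_DELAY] < 0
        if neg.any():
            if y[: IDX_DELAY].min() < -1e-6:
                raise IntegrationError(
                    f"negative bile acid amount beyond tolerance at t={t1:.1f} h "
                    f"(min {y[:IDX_DELAY].min():.3e} µmol)"
                )
            y[: IDX_DELAY][neg] = 0.0
            clip_events += 1
        all_t.append(t_eval[1:])
        all_y.append(ys[1:])
        administered.extend([given] * (len(t_eval) - 1))
        # meal event at t1: gallbladder empties into the gut lumen
        if t1 in meal_set:
            for s in range(N_SPECIES):
                moved = frac * y[5 * s + gb]
                y[5 * s + gb] -= moved
                y[5 * s + gut] += moved

    return ExposureTrace(
        times_h=np.concatenate(all_t),
        states=np.vstack(all_y),
        params=p,
        clip_events=clip_events,
        administered_umol=np.array(administered) if compound is not None else None,
        drug_names=(compound.species_names() if compound is not None else []),
    )
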