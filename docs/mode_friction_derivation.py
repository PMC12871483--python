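"""Derive the per-mode hydrodynamic friction for radial (shape) modes of a
spherical vesicle with inner viscosity eta_i, outer viscosity eta_o and an
incompressible membrane with Boussinesq-Scriven surface shear viscosity eta_m.

Mode l displacement u(theta,t) = s(t) P_l(cos theta).  The solvent flow is
kinematically determined by (i) v_r = s' P_l on both sides, (ii) tangential
velocity continuity, (iii) membrane incompressibility
div_s v_s + 2 v_r / R = 0.  Total dissipation P = Z_l s'^2 gives the friction
Z_l; the relaxation rate is Gamma_l = E''(s)/Z_l.

Validation: at eta_i = eta_o = eta, eta_m = 0 the result must reduce to the
Milner-Safran friction Z_l = 4 pi eta R (2 l^2 + 2 l - 1)/(l (l + 1)).
"""
import sympy as sp

r, th, R, U = sp.symbols('r theta R U', positive=True)
eta_i, eta_o, eta_m = sp.symbols('eta_i eta_o eta_m', positive=True)


def mode_friction(l):
    P = sp.legendre(l, sp.cos(th))
    dP = sp.diff(P, th)

    # ---- interior Stokes solution (regular at r=0) ----
    a1, a2 = sp.symbols('a1 a2')
    vr_i = (a1 * r**(l - 1) + a2 * r**(l + 1)) * P
    b1 = a1 / l
    b2 = a2 * (l + 3) / (l * (l + 1))
    vt_i = (b1 * r**(l - 1) + b2 * r**(l + 1)) * dP
    p_i = eta_i * 2 * (2 * l + 3) * a2 / l * r**l * P

    # ---- exterior Stokes solution (decays at infinity) ----
    A1, A2 = sp.symbols('A1 A2')
    vr_o = (A1 * r**(-l - 2) + A2 * r**(-l)) * P
    B1 = -A1 / (l + 1)
    B2 = A2 * (2 - l) / (l * (l + 1))
    vt_o = (B1 * r**(-l - 2) + B2 * r**(-l)) * dP
    # pressure harmonic of degree -(l+1); coefficient from r-momentum
    C2 = sp.symbols('C2')
    p_o = eta_o * C2 * r**(-l - 1) * P

    # verify momentum balance (eta lap v - grad p = 0) for both regions,
    # fixing C2 for the exterior
    def check_momentum(vr, vt, p, eta, sol_for=None):
        lap_r = (sp.diff(vr, r, 2) + 2 / r * sp.diff(vr, r)
                 + sp.diff(vr, th, 2) / r**2 + sp.cos(th) / sp.sin(th) * sp.diff(vr, th) / r**2
                 - 2 * vr / r**2 - 2 / r**2 * (sp.diff(vt, th) + sp.cos(th) / sp.sin(th) * vt))
        lap_t = (sp.diff(vt, r, 2) + 2 / r * sp.diff(vt, r)
                 + sp.diff(vt, th, 2) / r**2 + sp.cos(th) / sp.sin(th) * sp.diff(vt, th) / r**2
                 + 2 / r**2 * sp.diff(vr, th) - vt / (r**2 * sp.sin(th)**2))
        mr = sp.simplify(eta * lap_r - sp.diff(p, r))
        mt = sp.simplify(eta * lap_t - sp.diff(p, th) / r)
        if sol_for is not None:
            sol = sp.solve([sp.Eq(mr, 0)], [sol_for], dict=True)[0]
            mr = mr.subs(sol)
            mt = sp.simplify(mt.subs(sol))
            assert sp.simplify(mr) == 0 and sp.simplify(mt) == 0, (l, 'ext momentum')
            return sol
        assert sp.simplify(mr) == 0 and sp.simplify(mt) == 0, (l, 'int momentum')
        return None

    check_momentum(vr_i, vt_i, p_i, eta_i)
    sol_C2 = check_momentum(vr_o, vt_o, p_o, eta_o, sol_for=C2)
    p_o = p_o.subs(sol_C2)

    # ---- boundary conditions at r = R ----
    Vt = 2 * U / (l * (l + 1))     # membrane incompressibility
    sol_i = sp.solve([sp.Eq(vr_i.subs(r, R), U * P),
                      sp.Eq(vt_i.subs(r, R), Vt * dP)], [a1, a2], dict=True)[0]
    sol_o = sp.solve([sp.Eq(vr_o.subs(r, R), U * P),
                      sp.Eq(vt_o.subs(r, R), Vt * dP)], [A1, A2], dict=True)[0]

    def dissipation(vr, vt, eta, bounds):
        err = sp.diff(vr, r)
        ett = sp.diff(vt, th) / r + vr / r
        eff = vr / r + vt * sp.cos(th) / (r * sp.sin(th))
        ert = sp.Rational(1, 2) * (r * sp.diff(vt / r, r) + sp.diff(vr, th) / r)
        phi = 2 * eta * (err**2 + ett**2 + eff**2 + 2 * ert**2)
        ang = sp.integrate(sp.expand(phi * sp.sin(th)), (th, 0, sp.pi))
        return 2 * sp.pi * sp.integrate(ang * r**2, bounds)

    P_in = dissipation(vr_i.subs(sol_i), vt_i.subs(sol_i), eta_i, (r, 0, R))
    P_out = dissipation(vr_o.subs(sol_o), vt_o.subs(sol_o), eta_o, (r, R, sp.oo))

    # ---- membrane (surface) dissipation ----
    vs = Vt * dP
    vn = U * P
    ett_s = (sp.diff(vs, th) + vn) / R
    eff_s = (vs * sp.cos(th) / sp.sin(th) + vn) / R
    # incompressible surface: ett_s + eff_s == 0
    assert sp.simplify(sp.expand_trig(sp.simplify(ett_s + eff_s))) == 0, (l, 'surface incompressibility')
    phi_m = 2 * eta_m * (ett_s**2 + eff_s**2)
    P_mem = 2 * sp.pi * R**2 * sp.integrate(sp.expand(phi_m * sp.sin(th)), (th, 0, sp.pi))

    Z = sp.simplify((P_in + P_out + P_mem) / U**2)
    return sp.factor(sp.expand(Z))


results = {}
for l in range(2, 11):
    Z = mode_friction(l)
    results[l] = Z
    # decompose: Z = 4 pi R / (l(l+1)) * (eta_i*A + eta_o*B + eta_m/R*C)
    pref = 4 * sp.pi * R / (l * (l + 1))
    A = sp.simplify(Z.coeff(eta_i) / pref)
    B = sp.simplify(Z.coeff(eta_o) / pref)
    C = sp.simplify(Z.coeff(eta_m) * R / pref)
    ms = sp.simplify(A + B - (2 * l**2 + 2 * l - 1))
    print(f"l={l}: A={A}  B={B}  C={C}  (A+B)-MS={ms}")
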