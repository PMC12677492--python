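"""Builders for the four structural models of the triangulation battery.

All four operate on two constructs (generically X = curiosity, Y =
creativity) measured at T occasions, modelled as composite scores:

* ``build_riclpm`` — random-intercept cross-lagged panel model: stable
  trait factors plus autoregressive/cross-lagged dynamics among the
  within-person occasion residuals.
* ``build_riclpm_reversed`` — time-reversed variant in which earlier
  within-person residuals of the outcome are regressed on concurrent
  predictor residuals and on LATER outcome residuals.  Under a true
  increasing effect the concurrent coefficient should be negative (the
  compensation signature); spurious common-state data drive it positive.
* ``build_lcsm`` — bivariate latent change score model: each later score
  is defined as earlier score + latent change (both definitional paths
  fixed to 1), and the change factors are regressed on the other
  construct's previous level (coupling) and the own previous level
  (autoproportion).
* ``build_mosla`` — model of spurious longitudinal associations: trait
  factors plus occasion-specific auto-correlated state factors loading on
  both constructs, with NO directed path between the constructs.

For the canonical three-wave battery the builders reproduce the reference
degrees of freedom 5 / 5 / 12 / 9 against the 21 distinct covariance
moments of six observed variables; each builder checks its df target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sem_core import Entry, SemModelSpec


@dataclass
class PanelLayout:
    """Observed-variable naming for X and Y at occasions 1..T."""

    T: int = 3
    x_prefix: str = "x"
    y_prefix: str = "y"

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("panel layout needs at least two occasions")
        if self.x_prefix == self.y_prefix:
            raise ValueError("construct prefixes must differ")

    @property
    def x_names(self) -> list[str]:
        return [f"{self.x_prefix}{t}" for t in range(1, self.T + 1)]

    @property
    def y_names(self) -> list[str]:
        return [f"{self.y_prefix}{t}" for t in range(1, self.T + 1)]

    @property
    def observed(self) -> list[str]:
        return self.x_names + self.y_names

    def swapped(self) -> "PanelLayout":
        return PanelLayout(T=self.T, x_prefix=self.y_prefix, y_prefix=self.x_prefix)


def _check_df(spec: SemModelSpec, target: int | None) -> SemModelSpec:
    if target is not None and spec.df_on_full_moments != target:
        raise ValueError(
            f"{spec.name}: constraint pattern yields df="
            f"{spec.df_on_full_moments} (k={spec.k}), expected df={target}")
    return spec


# ---------------------------------------------------------------------------
# model 1: RI-CLPM
# ---------------------------------------------------------------------------

def build_riclpm(layout: PanelLayout, lag_constrained: bool = True) -> SemModelSpec:
    """Random-intercept cross-lagged panel model.

    Trait factors ``g_x, g_y`` load 1 on every occasion of their construct
    and covary freely; occasion residuals ``rx_t, ry_t`` carry all
    occasion-level variance (observed uniquenesses fixed 0).  Directed
    paths: autoregressions ``rx_t -> rx_{t+1}``, ``ry_t -> ry_{t+1}`` and
    cross-lags ``rx_t -> ry_{t+1}``, ``ry_t -> rx_{t+1}``.  With
    ``lag_constrained`` (default) the unstandardized paths are held equal
    across lags, which for T = 3 gives the reference df = 5; freeing them
    leaves df = 1.
    """
    T = layout.T
    xs, ys = layout.x_names, layout.y_names
    rx = [f"r_{v}" for v in xs]
    ry = [f"r_{v}" for v in ys]
    gx, gy = f"g_{layout.x_prefix}", f"g_{layout.y_prefix}"
    variables = xs + ys + [gx, gy] + rx + ry
    paths: dict[tuple[str, str], Entry] = {}
    covs: dict[tuple[str, str], Entry] = {}
    for t in range(T):
        paths[(xs[t], gx)] = 1.0
        paths[(ys[t], gy)] = 1.0
        paths[(xs[t], rx[t])] = 1.0
        paths[(ys[t], ry[t])] = 1.0
        covs[(xs[t], xs[t])] = 0.0
        covs[(ys[t], ys[t])] = 0.0
    covs[(gx, gx)] = "v_gx"
    covs[(gy, gy)] = "v_gy"
    covs[(gx, gy)] = "c_g"
    covs[(rx[0], rx[0])] = "v_rx1"
    covs[(ry[0], ry[0])] = "v_ry1"
    covs[(rx[0], ry[0])] = "c_r1"
    for t in range(T - 1):
        lag = "" if lag_constrained else f"_{t + 1}"
        paths[(rx[t + 1], rx[t])] = f"a_x{lag}"
        paths[(ry[t + 1], ry[t])] = f"a_y{lag}"
        paths[(ry[t + 1], rx[t])] = f"c_xy{lag}"
        paths[(rx[t + 1], ry[t])] = f"c_yx{lag}"
        covs[(rx[t + 1], rx[t + 1])] = f"v_rx{t + 2}"
        covs[(ry[t + 1], ry[t + 1])] = f"v_ry{t + 2}"
        covs[(rx[t + 1], ry[t + 1])] = f"c_r{t + 2}"
    spec = SemModelSpec(variables=variables, observed=layout.observed,
                        paths=paths, covs=covs, name="riclpm")
    target = 5 if (T == 3 and lag_constrained) else None
    return _check_df(spec, target)


def riclpm_crosslag_labels(layout: PanelLayout, direction: str = "xy",
                           lag_constrained: bool = True) -> list[tuple[str, str]]:
    """(target, source) residual pairs of the cross-lag paths, by lag order."""
    rx = [f"r_{v}" for v in layout.x_names]
    ry = [f"r_{v}" for v in layout.y_names]
    if direction == "xy":
        return [(ry[t + 1], rx[t]) for t in range(layout.T - 1)]
    return [(rx[t + 1], ry[t]) for t in range(layout.T - 1)]


# ---------------------------------------------------------------------------
# model 2: time-reversed RI-CLPM
# ---------------------------------------------------------------------------

def build_riclpm_reversed(layout: PanelLayout, both_directions: bool = False) -> SemModelSpec:
    """Time-reversed RI-CLPM (default: creativity-outcome direction only).

    Same trait/residual skeleton as :func:`build_riclpm`, but earlier
    outcome residuals are regressed on concurrent predictor residuals and
    on later outcome residuals: ``ry_t ~ rx_t + ry_{t+1}``.  The predictor
    construct keeps a forward autoregression.  Exogenous variables are the
    initial predictor residual and the final outcome residual, freely
    covarying; paths are free per lag.  For T = 3 this gives df = 5.

    ``both_directions=True`` instead reverses BOTH constructs and adds the
    mirrored concurrent paths in a single (nonrecursive) model.
    """
    T = layout.T
    xs, ys = layout.x_names, layout.y_names
    rx = [f"r_{v}" for v in xs]
    ry = [f"r_{v}" for v in ys]
    gx, gy = f"g_{layout.x_prefix}", f"g_{layout.y_prefix}"
    variables = xs + ys + [gx, gy] + rx + ry
    paths: dict[tuple[str, str], Entry] = {}
    covs: dict[tuple[str, str], Entry] = {}
    for t in range(T):
        paths[(xs[t], gx)] = 1.0
        paths[(ys[t], gy)] = 1.0
        paths[(xs[t], rx[t])] = 1.0
        paths[(ys[t], ry[t])] = 1.0
        covs[(xs[t], xs[t])] = 0.0
        covs[(ys[t], ys[t])] = 0.0
    covs[(gx, gx)] = "v_gx"
    covs[(gy, gy)] = "v_gy"
    covs[(gx, gy)] = "c_g"
    if not both_directions:
        # exogenous: rx_1 and ry_T
        covs[(rx[0], rx[0])] = "v_rx1"
        covs[(ry[T - 1], ry[T - 1])] = f"v_ry{T}"
        covs[(rx[0], ry[T - 1])] = "c_ex"
        for t in range(T - 1):
            paths[(rx[t + 1], rx[t])] = f"a_x_{t + 1}"          # forward AR, predictor
            paths[(ry[t], ry[t + 1])] = f"b_y_{t + 1}"          # reversed AR, outcome
            paths[(ry[t], rx[t])] = f"d_{t + 1}"                # concurrent cross path
            covs[(rx[t + 1], rx[t + 1])] = f"v_rx{t + 2}"
            covs[(ry[t], ry[t])] = f"v_ry{t + 1}"
        spec = SemModelSpec(variables=variables, observed=layout.observed,
                            paths=paths, covs=covs, name="riclpm_reversed")
        return _check_df(spec, 5 if T == 3 else None)
    # combined nonrecursive variant: both constructs reversed, reciprocal
    # concurrent paths at t = 1..T-1
    covs[(rx[T - 1], rx[T - 1])] = f"v_rx{T}"
    covs[(ry[T - 1], ry[T - 1])] = f"v_ry{T}"
    covs[(rx[T - 1], ry[T - 1])] = f"c_ex{T}"
    for t in range(T - 1):
        paths[(rx[t], rx[t + 1])] = f"b_x_{t + 1}"
        paths[(ry[t], ry[t + 1])] = f"b_y_{t + 1}"
        paths[(ry[t], rx[t])] = f"d_xy_{t + 1}"
        paths[(rx[t], ry[t])] = f"d_yx_{t + 1}"
        covs[(rx[t], rx[t])] = f"v_rx{t + 1}"
        covs[(ry[t], ry[t])] = f"v_ry{t + 1}"
    spec = SemModelSpec(variables=variables, observed=layout.observed,
                        paths=paths, covs=covs, name="riclpm_reversed_both")
    return spec


# ---------------------------------------------------------------------------
# model 3: bivariate latent change score model
# ---------------------------------------------------------------------------

def build_lcsm(layout: PanelLayout) -> SemModelSpec:
    """Bivariate latent change score model on the observed composites.

    Definitional structure: ``score_t = score_{t-1} + change_t`` with both
    regression weights fixed to 1, so each latent change factor IS the
    difference between adjacent scores.  Each change factor is regressed
    on the other construct's previous level (coupling, equal across lags)
    and on the own previous level (autoproportion, equal across lags);
    change variances are equal across occasions.  For T = 3: df = 12.
    """
    T = layout.T
    xs, ys = layout.x_names, layout.y_names
    dx = [f"d_{v}" for v in xs[1:]]
    dy = [f"d_{v}" for v in ys[1:]]
    variables = xs + ys + dx + dy
    paths: dict[tuple[str, str], Entry] = {}
    covs: dict[tuple[str, str], Entry] = {}
    covs[(xs[0], xs[0])] = "v_x1"
    covs[(ys[0], ys[0])] = "v_y1"
    covs[(xs[0], ys[0])] = "c_1"
    for t in range(1, T):
        paths[(xs[t], xs[t - 1])] = 1.0
        paths[(xs[t], dx[t - 1])] = 1.0
        paths[(ys[t], ys[t - 1])] = 1.0
        paths[(ys[t], dy[t - 1])] = 1.0
        covs[(xs[t], xs[t])] = 0.0
        covs[(ys[t], ys[t])] = 0.0
        # change regressed on own previous level and the other construct
        paths[(dx[t - 1], xs[t - 1])] = "phi_x"
        paths[(dx[t - 1], ys[t - 1])] = "gam_x"   # Y level -> change in X
        paths[(dy[t - 1], ys[t - 1])] = "phi_y"
        paths[(dy[t - 1], xs[t - 1])] = "gam_y"   # X level -> change in Y
        covs[(dx[t - 1], dx[t - 1])] = "v_dx"
        covs[(dy[t - 1], dy[t - 1])] = "v_dy"
    spec = SemModelSpec(variables=variables, observed=layout.observed,
                        paths=paths, covs=covs, name="lcsm")
    return _check_df(spec, 12 if T == 3 else None)


def lcsm_coupling_labels(direction: str = "xy") -> str:
    """Raw coupling label for predictor construct -> outcome change."""
    return "gam_y" if direction == "xy" else "gam_x"


# ---------------------------------------------------------------------------
# model 7: MoSLA
# ---------------------------------------------------------------------------

def build_mosla(layout: PanelLayout) -> SemModelSpec:
    """Model of spurious longitudinal associations.

    Trait factors with unit loadings on their own construct plus occasion
    state factors ``st_t`` loading 1 on X_t and a common free loading
    (equal across occasions) on Y_t, with first-order autoregression among
    the states (equal across lags).  The initial state variance and the
    state innovation variances share ONE label, and each observed score
    keeps an occasion-specific unique variance.  No directed path connects
    the two constructs.  For T = 3: 12 free parameters, df = 9.
    """
    T = layout.T
    if T < 3:
        raise ValueError("MoSLA needs at least three occasions")
    xs, ys = layout.x_names, layout.y_names
    st = [f"st{t}" for t in range(1, T + 1)]
    gx, gy = f"g_{layout.x_prefix}", f"g_{layout.y_prefix}"
    variables = xs + ys + [gx, gy] + st
    paths: dict[tuple[str, str], Entry] = {}
    covs: dict[tuple[str, str], Entry] = {}
    for t in range(T):
        paths[(xs[t], gx)] = 1.0
        paths[(ys[t], gy)] = 1.0
        paths[(xs[t], st[t])] = 1.0
        paths[(ys[t], st[t])] = "lam"
        covs[(xs[t], xs[t])] = f"u_x{t + 1}"
        covs[(ys[t], ys[t])] = f"u_y{t + 1}"
        covs[(st[t], st[t])] = "v_st"
    for t in range(T - 1):
        paths[(st[t + 1], st[t])] = "ar"
    covs[(gx, gx)] = "v_gx"
    covs[(gy, gy)] = "v_gy"
    covs[(gx, gy)] = "c_g"
    spec = SemModelSpec(variables=variables, observed=layout.observed,
                        paths=paths, covs=covs, name="mosla")
    spec.starts.update({"lam": 0.5, "ar": 0.3, "v_st": 0.3})
    return _check_df(spec, 9 if T == 3 else None)
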