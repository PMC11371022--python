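"""Nine-species water-radiolysis reaction-network kinetics.

Ionizing dose deposited in the cellular aqueous phase produces primary
radiolytic species (hydrated electrons, hydroxyl radicals, hydrogen atoms,
molecular hydrogen and peroxide) at rates set by their radiolytic yields
(G-values).  These feed a mass-action network in which carbon-centred
biomolecule radicals R* capture oxygen to form peroxyl radicals ROO*, the
proxy for lipid/DNA damage.  The time-integrated peroxyl exposure
(``roo_auc``) depends on both dose and dose rate: at ultra-high (FLASH)
dose rates, radical-radical recombination quenches the transiently high
radical concentrations before oxygen capture and slow detoxification can
act, so the same dose produces less cumulative ROO* exposure.

The normalized exposure surface N(D, Dr) tabulated from ODE runs is
compressed into a logistic-in-log10(dose rate) surrogate

    N(D, Dr) = 1 - a(D) / (1 + exp(-(log10 Dr - b(D)) / w))

with a(D), b(D) polynomials in dose and a shared transition width w.

Mass-action convention: a reaction ``2A -> B`` with rate constant k has
rate ``r = k [A]^2`` and consumes A at ``2r``.  G-values are in umol/J;
at unit water density a dose rate Dr (Gy/s) produces ``g * 1e-6 * Dr``
mol L^-1 s^-1 of each primary species while the beam is on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "IrradiationProtocol",
    "SolverControls",
    "KineticsResult",
    "ExposureSurface",
    "SurrogateModel",
    "assemble_rhs",
    "integrate",
    "exposure_surface",
    "fit_surrogate",
    "normalized_exposure",
    "load_network",
    "default_network",
]

#: mol/L produced per (umol/J G-value) per Gy at unit density
G_UNIT = 1e-6


class NetworkConfigError(ValueError):
    """Malformed network definition."""


class KineticsDomainError(ValueError):
    """Protocol or solver input outside its domain."""


class IntegrationError(RuntimeError):
    """Stiff integration failed; carries the protocol for diagnosis."""


@dataclass(frozen=True)
class Species:
    name: str
    description: str = ""
    initial_concentration: float = 0.0  # mol/L
    g_value: float = 0.0  # umol/J (per unit dose at unit density)

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise NetworkConfigError(f"{self.name}: negative initial concentration")
        if self.g_value < 0:
            raise NetworkConfigError(f"{self.name}: negative G-value")


_TERM = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(side: str):
    side = side.strip()
    if not side:
        return []
    terms = []
    for chunk in side.split("+"):
        m = _TERM.match(chunk)
        if m is None:
            raise NetworkConfigError(f"cannot parse reaction term {chunk!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        terms.append((m.group(2), coeff))
    return terms


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction of order 1 or 2."""

    reactants: tuple  # ((name, stoichiometry), ...)
    products: tuple
    rate_constant: float  # s^-1 (order 1) or L mol^-1 s^-1 (order 2)
    source: str = ""

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise NetworkConfigError("rate_constant must be positive")
        order = sum(s for _, s in self.reactants)
        if order not in (1, 2):
            raise NetworkConfigError(
                f"only order-1 and order-2 reactions are supported (got {order})"
            )

    @classmethod
    def from_equation(cls, equation: str, rate_constant: float, source: str = ""):
        if "->" not in equation:
            raise NetworkConfigError(f"missing '->' in {equation!r}")
        lhs, rhs = equation.split("->", 1)
        reactants = tuple(_parse_side(lhs))
        if not reactants:
            raise NetworkConfigError(f"no reactants in {equation!r}")
        return cls(reactants, tuple(_parse_side(rhs)), rate_constant, source)

    @property
    def equation(self) -> str:
        def fmt(terms):
            return " + ".join(
                (f"{s:g} {n}" if s != 1 else n) for n, s in terms
            )

        return f"{fmt(self.reactants)} -> {fmt(self.products)}"

    @property
    def order(self) -> int:
        return int(sum(s for _, s in self.reactants))


@dataclass(frozen=True)
class ReactionNetwork:
    """Species with radiolytic yields plus mass-action reactions."""

    species: tuple
    reactions: tuple
    name: str = "network"
    readout: str = "ROO"  # species whose exposure AUC is the damage proxy

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkConfigError("duplicate species names")
        known = set(names)
        for rxn in self.reactions:
            for n, _ in list(rxn.reactants) + list(rxn.products):
                if n not in known:
                    raise NetworkConfigError(
                        f"reaction {rxn.equation!r} references unknown species {n!r}"
                    )
        if self.readout not in known:
            raise NetworkConfigError(f"readout species {self.readout!r} not defined")

    @property
    def species_names(self) -> list:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    @property
    def g_values(self) -> np.ndarray:
        return np.array([s.g_value for s in self.species])

    # --- YAML round trip ------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "ReactionNetwork":
        try:
            species = tuple(
                Species(
                    name=str(s["name"]),
                    description=str(s.get("description", "")),
                    initial_concentration=float(s.get("initial", 0.0)),
                    g_value=float(s.get("g_value", 0.0)),
                )
                for s in doc["species"]
            )
            reactions = tuple(
                Reaction.from_equation(
                    r["equation"], float(r["k"]), str(r.get("source", ""))
                )
                for r in doc.get("reactions", [])
            )
        except (KeyError, TypeError) as exc:
            raise NetworkConfigError(f"malformed network definition: {exc}") from exc
        return cls(
            species=species,
            reactions=reactions,
            name=str(doc.get("name", "network")),
            readout=str(doc.get("readout", "ROO")),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "readout": self.readout,
            "species": [
                {
                    "name": s.name,
                    "description": s.description,
                    "initial": s.initial_concentration,
                    "g_value": s.g_value,
                }
                for s in self.species
            ],
            "reactions": [
                {"equation": r.equation, "k": r.rate_constant, "source": r.source}
                for r in self.reactions
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_network(path) -> ReactionNetwork:
    """Read a network definition YAML file."""
    return ReactionNetwork.from_yaml(path)


def default_network() -> ReactionNetwork:
    """The packaged nine-species water-radiolysis network."""
    from importlib.resources import files

    with files("flashsr.data").joinpath("water_radiolysis.yaml").open() as fh:
        return ReactionNetwork.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class IrradiationProtocol:
    """A continuous irradiation block of dose D at dose rate Dr.

    The beam is on for ``duration = D / Dr`` seconds and the system then
    relaxes for ``post_irradiation_followup`` seconds.
    """

    dose: float  # Gy
    dose_rate: float  # Gy/s
    mode: str = "continuous"
    post_irradiation_followup: float = 100.0  # s

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise KineticsDomainError("dose must be nonnegative (Gy)")
        if self.dose_rate <= 0:
            raise KineticsDomainError("dose_rate must be positive (Gy/s)")
        if self.mode not in ("continuous", "single-block"):
            raise KineticsDomainError(f"unknown mode {self.mode!r}")
        if self.post_irradiation_followup < 0:
            raise KineticsDomainError("followup must be nonnegative (s)")

    @property
    def duration(self) -> float:
        """Beam-on time D / Dr in seconds."""
        return self.dose / self.dose_rate


@dataclass(frozen=True)
class SolverControls:
    rtol: float = 1e-8
    atol: float = 1e-15  # mol/L
    method: str = "BDF"
    n_points_irradiation: int = 257
    n_points_followup: int = 257


@dataclass(frozen=True)
class KineticsResult:
    """Time courses plus the peroxyl-exposure readout."""

    time_grid: np.ndarray  # s
    concentrations: dict  # name -> mol/L array
    roo_auc: float  # mol s / L, integral of the readout species
    protocol: IrradiationProtocol

    def auc(self, species: str) -> float:
        """Trapezoidal AUC of any species on the output grid."""
        return float(np.trapezoid(self.concentrations[species], self.time_grid))

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time_s, species, concentration_M) table."""
        frames = [
            pd.DataFrame(
                {"time_s": self.time_grid, "species": name, "concentration_M": conc}
            )
            for name, conc in self.concentrations.items()
        ]
        return pd.concat(frames, ignore_index=True)


def _mass_action_terms(network: ReactionNetwork):
    """Precompute (reactant indices, stoichs, k, net stoichiometry vector)."""
    n = len(network.species)
    compiled = []
    for rxn in network.reactions:
        idx = np.array([network.index(name) for name, _ in rxn.reactants])
        st = np.array([s for _, s in rxn.reactants])
        net = np.zeros(n)
        for name, s in rxn.reactants:
            net[network.index(name)] -= s
        for name, s in rxn.products:
            net[network.index(name)] += s
        compiled.append((idx, st, rxn.rate_constant, net))
    return compiled


def _make_rhs(network: ReactionNetwork, production: np.ndarray):
    """RHS with a fixed (possibly zero) production vector, mol/L/s."""
    terms = _mass_action_terms(network)

    def rhs(t, y):
        dy = production.copy()
        for idx, st, k, net in terms:
            rate = k * np.prod(y[idx] ** st)
            dy += net * rate
        return dy

    return rhs


def _make_jacobian(network: ReactionNetwork):
    """Analytic Jacobian of the mass-action terms (production is constant)."""
    terms = _mass_action_terms(network)
    n = len(network.species)

    def jac(t, y):
        j = np.zeros((n, n))
        for idx, st, k, net in terms:
            for pos, i in enumerate(idx):
                # d(rate)/dy_i for rate = k * prod y^st
                drate = k * st[pos] * y[i] ** (st[pos] - 1)
                for q, iq in enumerate(idx):
                    if q != pos:
                        drate *= y[iq] ** st[q]
                j[:, i] += net * drate
        return j

    return jac


def assemble_rhs(network: ReactionNetwork, protocol: IrradiationProtocol):
    """Derivative function d[S]/dt(t, y) for the irradiated network.

    Radiolytic production ``g * 1e-6 * Dr`` (mol/L/s) is active while
    ``t < D / Dr`` and switches off once the dose has been delivered;
    mass-action terms act at all times.
    """
    production = network.g_values * G_UNIT * protocol.dose_rate
    beam_on = _make_rhs(network, production)
    beam_off = _make_rhs(network, np.zeros(len(network.species)))
    t_end = protocol.duration

    def rhs(t, y):
        return beam_on(t, y) if t < t_end else beam_off(t, y)

    return rhs


def _integrate_leg(rhs, t0, t1, y0, t_eval, controls, protocol, jac=None):
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method=controls.method,
        rtol=controls.rtol,
        atol=controls.atol,
        t_eval=t_eval,
        jac=jac,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed for D={protocol.dose} Gy at "
            f"Dr={protocol.dose_rate} Gy/s: {sol.message}"
        )
    return sol


def integrate(
    network: ReactionNetwork,
    protocol: IrradiationProtocol,
    controls: SolverControls | None = None,
) -> KineticsResult:
    """Stiff integration of the network over irradiation plus followup.

    The readout exposure is computed as an auxiliary quadrature state
    (d/dt of the running integral equals the readout concentration), so
    ``roo_auc`` carries the integrator's tolerance rather than a
    sampling-grid error.  The two legs (beam on, beam off) are integrated
    separately so the production discontinuity never sits inside a step.
    """
    controls = controls or SolverControls()
    n = len(network.species)
    ridx = network.index(network.readout)

    production = np.zeros(n + 1)
    production[:n] = network.g_values * G_UNIT * protocol.dose_rate
    base_on = _make_rhs(network, production[:n])
    base_off = _make_rhs(network, np.zeros(n))

    def augmented(base):
        def rhs(t, y):
            dy = np.empty(n + 1)
            dy[:n] = base(t, y[:n])
            dy[n] = y[ridx]
            return dy

        return rhs

    base_jac = _make_jacobian(network)

    def augmented_jac(t, y):
        j = np.zeros((n + 1, n + 1))
        j[:n, :n] = base_jac(t, y[:n])
        j[n, ridx] = 1.0
        return j

    y0 = np.append(network.initial_state, 0.0)
    t_irr = protocol.duration
    followup = protocol.post_irradiation_followup

    times = []
    states = []
    if t_irr > 0:
        grid1 = np.linspace(0.0, t_irr, controls.n_points_irradiation)
        sol1 = _integrate_leg(
            augmented(base_on), 0.0, t_irr, y0, grid1, controls, protocol,
            jac=augmented_jac,
        )
        times.append(sol1.t)
        states.append(sol1.y)
        y0 = sol1.y[:, -1].copy()
    if followup > 0:
        # log-spaced followup grid: the post-beam decay spans decades
        grid2 = t_irr + np.geomspace(
            max(followup * 1e-9, 1e-12), followup, controls.n_points_followup
        )
        sol2 = _integrate_leg(
            augmented(base_off),
            t_irr,
            t_irr + followup,
            y0,
            grid2,
            controls,
            protocol,
            jac=augmented_jac,
        )
        times.append(sol2.t)
        states.append(sol2.y)
    if not times:
        times = [np.array([0.0])]
        states = [y0[:, None]]

    t = np.concatenate(times)
    y = np.concatenate(states, axis=1)

    floor = -max(1e3 * controls.atol, 1e-12)
    if np.min(y[:n]) < floor:
        raise IntegrationError(
            f"negative concentration {np.min(y[:n]):.3e} beyond tolerance for "
            f"D={protocol.dose} Gy, Dr={protocol.dose_rate} Gy/s"
        )

    concentrations = {
        name: y[i] for i, name in enumerate(network.species_names)
    }
    return KineticsResult(
        time_grid=t,
        concentrations=concentrations,
        roo_auc=float(y[n, -1]),
        protocol=protocol,
    )


@dataclass(frozen=True)
class ExposureSurface:
    """Normalized peroxyl exposure N(D, Dr) tabulated from ODE runs.

    Each dose row is normalized by its value at the lowest dose rate of
    the grid (the conventional-dose-rate plateau), so N = 1 in the first
    column by construction and N in (0, 1] everywhere.
    """

    dose_grid: np.ndarray  # Gy
    dose_rate_grid: np.ndarray  # Gy/s, ascending, log-spaced
    raw_auc: np.ndarray  # (n_dose, n_rate) mol s / L
    normalized_exposure: np.ndarray  # (n_dose, n_rate), in (0, 1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.normalized_exposure,
            index=pd.Index(self.dose_grid, name="dose_Gy"),
            columns=[f"{r:.6g}" for r in self.dose_rate_grid],
        )
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def exposure_surface(
    network: ReactionNetwork,
    dose_grid: np.ndarray,
    dose_rate_grid: np.ndarray,
    followup: float = 100.0,
    controls: SolverControls | None = None,
) -> ExposureSurface:
    """Tabulate N(D, Dr) over a dose x dose-rate grid.

    Runs one stiff integration per grid point and normalizes each dose
    row by its lowest-dose-rate exposure.
    """
    doses = np.asarray(dose_grid, dtype=float)
    rates = np.asarray(dose_rate_grid, dtype=float)
    if doses.size == 0 or rates.size == 0:
        raise KineticsDomainError("empty grid")
    if np.any(doses <= 0) or np.any(rates <= 0):
        raise KineticsDomainError("dose and dose-rate grids must be positive")
    if np.any(np.diff(rates) <= 0):
        raise KineticsDomainError("dose_rate_grid must be strictly ascending")

    raw = np.empty((doses.size, rates.size))
    for i, d in enumerate(doses):
        for j, r in enumerate(rates):
            protocol = IrradiationProtocol(
                dose=d, dose_rate=r, post_irradiation_followup=followup
            )
            try:
                raw[i, j] = integrate(network, protocol, controls).roo_auc
            except IntegrationError as exc:
                raise IntegrationError(
                    f"surface point (D={d} Gy, Dr={r} Gy/s) failed: {exc}"
                ) from exc
    anchor = raw[:, [0]]
    if np.any(anchor <= 0):
        raise IntegrationError(
            "zero exposure at the low-dose-rate anchor; cannot normalize"
        )
    normalized = np.clip(raw / anchor, None, 1.0)
    return ExposureSurface(doses, rates, raw, normalized)


@dataclass(frozen=True)
class SurrogateModel:
    """Logistic-in-log10(Dr) compression of an exposure surface.

    ``N(D, Dr) = 1 - a(D) * expit((log10 Dr - b(D)) / w)`` with a, b
    polynomials in dose (coefficients in ascending degree order).
    """

    a_coefficients: np.ndarray
    b_coefficients: np.ndarray
    width: float  # w, decades
    max_residual: float = np.nan
    dose_range: tuple = (0.0, np.inf)  # fitted support, for documentation

    def a(self, dose) -> np.ndarray:
        return np.polynomial.polynomial.polyval(dose, self.a_coefficients)

    def b(self, dose) -> np.ndarray:
        return np.polynomial.polynomial.polyval(dose, self.b_coefficients)

    def to_dict(self) -> dict:
        return {
            "a_coefficients": [float(c) for c in self.a_coefficients],
            "b_coefficients": [float(c) for c in self.b_coefficients],
            "width": float(self.width),
            "max_residual": float(self.max_residual),
            "dose_range": [float(self.dose_range[0]), float(self.dose_range[1])],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SurrogateModel":
        return cls(
            a_coefficients=np.asarray(doc["a_coefficients"], dtype=float),
            b_coefficients=np.asarray(doc["b_coefficients"], dtype=float),
            width=float(doc["width"]),
            max_residual=float(doc.get("max_residual", np.nan)),
            dose_range=tuple(doc.get("dose_range", (0.0, np.inf))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"surrogate": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc.get("surrogate", doc))


def _surrogate_eval(a_co, b_co, w, dose, log_rate):
    a = np.polynomial.polynomial.polyval(dose, a_co)
    b = np.polynomial.polynomial.polyval(dose, b_co)
    return 1.0 - a * expit((log_rate - b) / w)


def fit_surrogate(
    surface: ExposureSurface, poly_degree: int = 3
) -> SurrogateModel:
    """Least-squares fit of the logistic surrogate to a tabulated surface.

    Returns polynomial coefficients for the FLASH-sparing amplitude a(D)
    and log10 midpoint b(D), the shared width w, and the maximum absolute
    residual over the grid.
    """
    if poly_degree < 1:
        raise KineticsDomainError("poly_degree must be >= 1")
    doses = surface.dose_grid
    log_rates = np.log10(surface.dose_rate_grid)
    n_grid = surface.normalized_exposure
    deg = min(poly_degree, doses.size - 1)

    # row-wise initial guesses: amplitude from the high-rate asymptote,
    # midpoint from the half-amplitude crossing
    a_rows = 1.0 - n_grid[:, -1]
    b_rows = np.empty(doses.size)
    for i in range(doses.size):
        half = 1.0 - 0.5 * a_rows[i]
        b_rows[i] = np.interp(-half, -n_grid[i], log_rates)
    a0 = np.polynomial.polynomial.polyfit(doses, np.clip(a_rows, 1e-6, None), deg)
    b0 = np.polynomial.polynomial.polyfit(doses, b_rows, deg)
    x0 = np.concatenate([a0, b0, [0.5]])

    dd, ll = np.meshgrid(doses, log_rates, indexing="ij")

    def residuals(x):
        a_co = x[: deg + 1]
        b_co = x[deg + 1 : 2 * deg + 2]
        w = x[-1]
        return (_surrogate_eval(a_co, b_co, w, dd, ll) - n_grid).ravel()

    lower = np.full(x0.size, -np.inf)
    upper = np.full(x0.size, np.inf)
    lower[-1], upper[-1] = 0.02, 5.0  # width in decades
    result = least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-14,
                           ftol=1e-14, gtol=1e-14)
    if not result.success and result.status <= 0:
        raise RuntimeError(
            f"surrogate fit did not converge: {result.message}; "
            f"residual norm {np.linalg.norm(result.fun):.3e}"
        )
    a_co = result.x[: deg + 1]
    b_co = result.x[deg + 1 : 2 * deg + 2]
    w = float(result.x[-1])
    max_res = float(np.max(np.abs(result.fun)))
    return SurrogateModel(
        a_coefficients=a_co,
        b_coefficients=b_co,
        width=w,
        max_residual=max_res,
        dose_range=(float(doses.min()), float(doses.max())),
    )


def normalized_exposure(
    surrogate: SurrogateModel, dose, dose_rate
):
    """Evaluate the surrogate N(D, Dr), clamped to (0, 1].

    Scalar or array inputs broadcast; dose rates must be positive.
    """
    dose = np.asarray(dose, dtype=float)
    dose_rate = np.asarray(dose_rate, dtype=float)
    if np.any(dose_rate <= 0):
        raise KineticsDomainError("dose_rate must be positive (Gy/s)")
    value = _surrogate_eval(
        surrogate.a_coefficients,
        surrogate.b_coefficients,
        surrogate.width,
        dose,
        np.log10(dose_rate),
    )
    out = np.clip(value, 1e-12, 1.0)
    return float(out) if out.ndim == 0 else out
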