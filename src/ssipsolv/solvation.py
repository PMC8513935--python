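"""Free-energy mathematics of the SSIP solvation model.

A solute SSIP with donor polarity alpha transferred into a simple
(one-site-pair) solvent gains

    dg_S(alpha) = -alpha * beta_S - C_beta      (kJ/mol)

and an acceptor SSIP with polarity beta gains

    dg_S(beta)  = -alpha_S * beta - C_alpha.

Two-domain (polar) solvents expose a non-polar site pair (subscript 1)
and a polar site pair (subscript 2).  A solute donor equilibrates
between the two acceptor sites with effective equilibrium constants

    K_i = exp((alpha * beta_Si + C_beta_i) / RT),

and the solvation free energy is the population-weighted effective
constant, combined inside the logarithm:

    dg_S(alpha) = -RT ln(f_beta1 * K_1 + f_beta2 * K_2),

where the fractions f are the member solvent's acceptor-site fractions.
Solute acceptors mirror this with the donor sites and donor fractions.

Whole-molecule solvation sums per-SSIP terms and subtracts the solvent
offset C0 (positive C0 favours that solvent relative to n-hexadecane);
transfer between solvents is the difference of the two totals, and
log P = -dG/(RT ln 10), i.e. log10 of the destination-over-origin
concentration ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .errors import NumericError, UnsupportedFeatureError
from .parameters import (
    ACCEPTOR,
    DONOR,
    DEFAULT_REGISTRY,
    Registry,
    SimpleSolvent,
    Solvent,
    TwoDomainSolvent,
)
from .assignment import SSIPProfile


@dataclass(frozen=True)
class SolvationBreakdown:
    """Per-SSIP decomposition of a molecular solvation free energy."""

    solvent: str
    contributions: tuple[tuple[str, str, float, float], ...]  # (label, role, value, dg)
    ssip_sum: float  # kJ/mol, sum of per-SSIP terms
    c0_term: float  # kJ/mol, -C0
    total: float  # kJ/mol, ssip_sum + c0_term

    def __post_init__(self) -> None:
        if not math.isclose(self.total, self.ssip_sum + self.c0_term, abs_tol=1e-12):
            raise NumericError("breakdown total does not equal its parts")


@dataclass(frozen=True)
class TransferResult:
    """Transfer free energy of a solute between two solvents."""

    solute: str
    solvent_from: str
    solvent_to: str
    dg: float  # kJ/mol
    logp: float  # log10([solute]_to / [solute]_from)


@dataclass(frozen=True)
class ComplexationResult:
    """1:1 H-bond complexation between a donor and an acceptor site."""

    alpha: float
    beta: float
    solvent: str
    dg: float  # kJ/mol
    k: float  # association constant, M^-1 (1 M standard state)


def dg_alpha_simple(
    alpha: float,
    solvent: SimpleSolvent,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Solvation free energy of one donor SSIP in a simple solvent (kJ/mol)."""
    return -alpha * solvent.beta_s - solvent.c_beta


def dg_beta_simple(
    beta: float,
    solvent: SimpleSolvent,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Solvation free energy of one acceptor SSIP in a simple solvent (kJ/mol)."""
    return -solvent.alpha_s * beta - solvent.c_alpha


def _dg_two_site(
    polarity: float,
    s1: tuple[float, float],
    s2: tuple[float, float] | None,
    f1: float,
    f2: float,
    rt: float,
) -> float:
    """-RT ln of the fraction-weighted effective equilibrium constant.

    ``s1``/``s2`` are (site polarity, site constant) pairs for the two
    solvent domains.  With f2 == 0 or degenerate sites this reduces
    exactly to the simple-solvent expression.
    """
    k1 = math.exp((polarity * s1[0] + s1[1]) / rt)
    if f2 == 0.0:
        return -rt * math.log(k1)
    if s2 is None or s2[0] is None or s2[1] is None:
        raise NumericError(
            "polar domain has interacting fraction > 0 but no registered site"
        )
    k2 = math.exp((polarity * s2[0] + s2[1]) / rt)
    return -rt * math.log(f1 * k1 + f2 * k2)


def dg_alpha_polar(
    alpha: float,
    solvent: TwoDomainSolvent,
    member: str,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Solvation free energy of one donor SSIP in a two-domain solvent (kJ/mol)."""
    f = solvent.fractions(member)
    return _dg_two_site(
        alpha,
        (solvent.beta_s1, solvent.c_beta1),
        (solvent.beta_s2, solvent.c_beta2),
        f.f_beta1,
        f.f_beta2,
        constants.rt,
    )


def dg_beta_polar(
    beta: float,
    solvent: TwoDomainSolvent,
    member: str,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Solvation free energy of one acceptor SSIP in a two-domain solvent (kJ/mol)."""
    f = solvent.fractions(member)
    s2 = (
        None
        if solvent.alpha_s2 is None
        else (solvent.alpha_s2, solvent.c_alpha2)
    )
    return _dg_two_site(
        beta,
        (solvent.alpha_s1, solvent.c_alpha1),
        s2,
        f.f_alpha1,
        f.f_alpha2,
        constants.rt,
    )


def _resolve(
    solvent: Solvent | str,
    member: str | None,
    registry: Registry,
) -> tuple[Solvent, str | None, str]:
    """Normalise a solvent argument to (object, member, display name)."""
    if isinstance(solvent, str):
        obj, resolved = registry.resolve_solvent(solvent)
        member = member or resolved
    else:
        obj = solvent
    if isinstance(obj, TwoDomainSolvent):
        if member is None:
            raise UnsupportedFeatureError(
                f"two-domain solvent class {obj.class_name!r} needs a member "
                f"solvent (one of: {', '.join(obj.member_names)})"
            )
        name = member
    else:
        name = obj.name
    return obj, member, name


def solvation_free_energy(
    profile: SSIPProfile,
    solvent: Solvent | str,
    member: str | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    registry: Registry | None = None,
) -> SolvationBreakdown:
    """Whole-molecule solvation free energy relative to the non-solvated state.

    Sums the per-SSIP terms over all donors and acceptors and subtracts
    the solvent offset C0 once per molecule.
    """
    registry = registry or DEFAULT_REGISTRY
    obj, member, name = _resolve(solvent, member, registry)

    contribs: list[tuple[str, str, float, float]] = []
    for s in profile.ssips:
        if isinstance(obj, SimpleSolvent):
            dg = (
                dg_alpha_simple(s.value, obj, constants)
                if s.role == DONOR
                else dg_beta_simple(s.value, obj, constants)
            )
        else:
            dg = (
                dg_alpha_polar(s.value, obj, member, constants)
                if s.role == DONOR
                else dg_beta_polar(s.value, obj, member, constants)
            )
        contribs.append((s.label, s.role, s.value, dg))

    ssip_sum = sum(c[3] for c in contribs)
    c0_term = -obj.c0
    return SolvationBreakdown(
        solvent=name,
        contributions=tuple(contribs),
        ssip_sum=ssip_sum,
        c0_term=c0_term,
        total=ssip_sum + c0_term,
    )


def transfer_free_energy(
    profile: SSIPProfile,
    solvent_from: Solvent | str,
    solvent_to: Solvent | str,
    member_from: str | None = None,
    member_to: str | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    registry: Registry | None = None,
) -> TransferResult:
    """Free energy of transfer S1 -> S2 and the matching partition coefficient.

    dG(S1 -> S2) = dG*(S2) - dG*(S1); log P = -dG/(RT ln 10) with the
    destination-over-origin concentration convention, so a negative dG
    (favourable transfer into S2) gives a positive log P.
    """
    registry = registry or DEFAULT_REGISTRY
    g_from = solvation_free_energy(profile, solvent_from, member_from, constants, registry)
    g_to = solvation_free_energy(profile, solvent_to, member_to, constants, registry)
    dg = g_to.total - g_from.total
    logp = -dg / (constants.rt * math.log(10.0))
    return TransferResult(
        solute=profile.molecule_id or profile.smiles,
        solvent_from=g_from.solvent,
        solvent_to=g_to.solvent,
        dg=dg,
        logp=logp,
    )


def complexation_dg(
    alpha: float,
    beta: float,
    solvent: SimpleSolvent | str,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    registry: Registry | None = None,
) -> ComplexationResult:
    """1:1 H-bond complexation free energy in a simple solvent.

    dG = -alpha*beta + alpha*beta_S + alpha_S*beta + C_alpha + C_beta.
    The model is validated against 1:1 complexation data in non-polar
    solvents only, so two-domain solvents are refused.
    """
    registry = registry or DEFAULT_REGISTRY
    if isinstance(solvent, str):
        solvent, _ = registry.resolve_solvent(solvent)
    if isinstance(solvent, TwoDomainSolvent):
        raise UnsupportedFeatureError(
            "1:1 complexation free energies are only defined for simple "
            f"(non-polar) solvents, not the {solvent.class_name} class"
        )
    dg = (
        -alpha * beta
        + alpha * solvent.beta_s
        + solvent.alpha_s * beta
        + solvent.c_alpha
        + solvent.c_beta
    )
    k = math.exp(-dg / constants.rt)
    return ComplexationResult(alpha=alpha, beta=beta, solvent=solvent.name, dg=dg, k=k)


def complexation_dg_reference(
    alpha: float,
    beta: float,
    solvent: SimpleSolvent,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Solvent-competition form: dG = -(alpha - alpha_S)(beta - beta_S) + 6.

    Equivalent to :func:`complexation_dg` whenever the solvent constants
    satisfy C_alpha + C_beta = 6 - alpha_S * beta_S (i.e. RT ln[S.S] = 6).
    Exposed for comparison; the +6 constant is the non-polar reference
    solvent-solvent entropy term.
    """
    return (
        -(alpha - solvent.alpha_s) * (beta - solvent.beta_s)
        + constants.reference_ss_entropy
    )


def rt_ln_ss(
    solvent: SimpleSolvent | TwoDomainSolvent,
    domain: int | None = None,
) -> float:
    """Back-calculated RT ln[S.S] from a solvent's constants (kJ/mol).

    C_alpha + C_beta = -alpha_S*beta_S + RT ln[S.S], so the left side
    plus alpha_S*beta_S recovers the solvent-solvent term.  For a
    two-domain solvent pass ``domain=1`` (non-polar) or ``domain=2``
    (polar) to apply the relation to that site pair.
    """
    if isinstance(solvent, TwoDomainSolvent):
        if domain == 1:
            return solvent.c_alpha1 + solvent.c_beta1 + solvent.alpha_s1 * solvent.beta_s1
        if domain == 2:
            if solvent.alpha_s2 is None:
                raise UnsupportedFeatureError(
                    f"the {solvent.class_name} class has no polar donor site"
                )
            return solvent.c_alpha2 + solvent.c_beta2 + solvent.alpha_s2 * solvent.beta_s2
        raise ValueError("specify domain=1 or domain=2 for a two-domain solvent")
    return solvent.c_alpha + solvent.c_beta + solvent.alpha_s * solvent.beta_s


def constants_from_ss(
    alpha_s: float,
    beta_s: float,
    ss_concentration: float | None = None,
    *,
    rt_ln_ss_value: float | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Solvent constants for a single-interaction-type solvent.

    For solvents whose donor and acceptor sites make one type of
    solvent-solvent interaction (alkanes, CCl4, perfluoroalkanes,
    water), C_alpha = C_beta = (-alpha_S*beta_S + RT ln[S.S]) / 2.
    Provide either the effective interaction concentration [S.S] in M
    or the RT ln[S.S] value directly in kJ/mol.
    """
    if (ss_concentration is None) == (rt_ln_ss_value is None):
        raise ValueError("provide exactly one of ss_concentration or rt_ln_ss_value")
    if rt_ln_ss_value is None:
        rt_ln_ss_value = constants.rt_ln(ss_concentration)
    c = (-alpha_s * beta_s + rt_ln_ss_value) / 2.0
    return c, c
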