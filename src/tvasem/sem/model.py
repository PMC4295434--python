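"""Declarative SEM model graphs in RAM form (A, S, filter).

A model is a set of variables (observed and latent), directed regression /
loading edges collected in the asymmetric matrix ``A``, and variances and
covariances collected in the symmetric matrix ``S``.  For an endogenous
variable the diagonal S entry is its residual variance; an off-diagonal S
entry between two endogenous variables is a residual covariance.  Residuals
can therefore be addressed by name (``e_TVA_C``) or by position (``e3`` =
residual of the third endogenous variable) without being explicit nodes.

The plain-text spec format, one statement per line (``#`` comments)::

    latent: Speed Capacity
    path: Speed -> TVA_C = 1      # fixed loading
    path: Age -> Speed            # free path
    path: Age -> Speed ~ 0.5      # free path with start value
    cov: e_TVA_C <-> e_TVA_K      # free residual covariance
    cov: A <-> B = 0.3            # fixed covariance
    var: Age = 1                  # fixed variance (latent scaling etc.)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["Parameter", "SemModel", "parse_model_spec"]


@dataclass(frozen=True)
class Parameter:
    """One entry of A or S: either free (estimated) or fixed to a value."""

    name: str
    matrix: str  # "A", "S" or "mean"
    row: int
    col: int
    free: bool
    value: float | None = None  # fixed value when not free
    start: float | None = None


class SemModel:
    """Validated structural model over named variables."""

    def __init__(
        self,
        observed_vars: list[str],
        latent_vars: list[str],
        paths: list[tuple[str, str, float | None, float | None]],
        covariances: list[tuple[str, str, float | None]] | None = None,
        fixed_variances: dict[str, float] | None = None,
    ):
        self.observed_vars = list(observed_vars)
        self.latent_vars = list(latent_vars)
        self.paths = [tuple(p) for p in paths]
        self.covariances = [tuple(c) for c in (covariances or [])]
        self.fixed_variances = dict(fixed_variances or {})
        self.variables = self.observed_vars + self.latent_vars
        self._validate()
        self._build_parameters()

    # -- structure ---------------------------------------------------------

    @property
    def endogenous(self) -> list[str]:
        """Targets of directed edges, in order of first appearance."""
        seen: list[str] = []
        for _, tgt, _, _ in self.paths:
            if tgt not in seen:
                seen.append(tgt)
        return seen

    def resolve_residual(self, token: str) -> str:
        """Map a residual token (``e_X`` or ``eN``) to its endogenous variable."""
        if token.startswith("e_"):
            v = token[2:]
            if v not in self.endogenous:
                raise ValueError(f"{token} does not name the residual of an endogenous variable")
            return v
        m = re.fullmatch(r"e(\d+)", token)
        if m:
            idx = int(m.group(1)) - 1
            endo = self.endogenous
            if not 0 <= idx < len(endo):
                raise ValueError(f"{token} out of range (model has {len(endo)} endogenous variables)")
            return endo[idx]
        raise ValueError(f"not a residual token: {token}")

    def _validate(self) -> None:
        if not self.variables:
            raise ValueError("empty model: no variables")
        if len(set(self.variables)) != len(self.variables):
            dup = [v for v in self.variables if self.variables.count(v) > 1]
            raise ValueError(f"duplicate variable names: {sorted(set(dup))}")
        known = set(self.variables)
        for src, tgt, *_ in self.paths:
            for v in (src, tgt):
                if v not in known:
                    raise ValueError(f"unknown variable in path: {v}")
        for a, b, *_ in self.covariances:
            for v in (a, b):
                if v not in known:
                    raise ValueError(f"unknown variable in covariance: {v}")
        for v in self.fixed_variances:
            if v not in known:
                raise ValueError(f"unknown variable in fixed variance: {v}")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((s, t) for s, t, *_ in self.paths)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"directed edges contain a cycle: {cyc}")
        seen_edges = set()
        for s, t, *_ in self.paths:
            if (s, t) in seen_edges:
                raise ValueError(f"duplicate path {s} -> {t}")
            seen_edges.add((s, t))
        # each latent must be scaled: a fixed outgoing loading or a fixed variance
        for lv in self.latent_vars:
            fixed_out = any(s == lv and fx is not None for s, _, fx, _ in self.paths)
            if not fixed_out and lv not in self.fixed_variances:
                raise ValueError(
                    f"latent {lv!r} is not scaled (needs a fixed outgoing loading or fixed variance)"
                )

    # -- parameters --------------------------------------------------------

    def _build_parameters(self) -> None:
        idx = {v: i for i, v in enumerate(self.variables)}
        self.var_index = idx
        endo = set(self.endogenous)
        params: list[Parameter] = []
        for src, tgt, fixed, start in self.paths:
            params.append(
                Parameter(
                    name=f"{src}->{tgt}",
                    matrix="A",
                    row=idx[tgt],
                    col=idx[src],
                    free=fixed is None,
                    value=fixed,
                    start=start,
                )
            )
        for v in self.variables:
            name = f"var(e_{v})" if v in endo else f"var({v})"
            fixed = self.fixed_variances.get(v)
            params.append(
                Parameter(
                    name=name,
                    matrix="S",
                    row=idx[v],
                    col=idx[v],
                    free=fixed is None,
                    value=fixed,
                )
            )
        for a, b, fixed in self.covariances:
            ea = f"e_{a}" if a in endo else a
            eb = f"e_{b}" if b in endo else b
            params.append(
                Parameter(
                    name=f"{ea}<->{eb}",
                    matrix="S",
                    row=idx[a],
                    col=idx[b],
                    free=fixed is None,
                    value=fixed,
                )
            )
        self.parameters = params
        self.free_parameters = [p for p in params if p.free]
        self.n_free = len(self.free_parameters)

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.free_parameters]

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(A, S) for a free-parameter vector ``theta``."""
        nv = len(self.variables)
        A = np.zeros((nv, nv))
        S = np.zeros((nv, nv))
        it = iter(theta)
        for p in self.parameters:
            val = next(it) if p.free else p.value
            if p.matrix == "A":
                A[p.row, p.col] = val
            else:
                S[p.row, p.col] = val
                S[p.col, p.row] = val
        return A, S

    def total_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Model-implied covariance over all variables: (I-A)^-1 S (I-A)^-T."""
        A, S = self.matrices(theta)
        nv = len(self.variables)
        IA = np.eye(nv) - A
        try:
            B = np.linalg.inv(IA)
        except np.linalg.LinAlgError as err:  # DAG check makes this unreachable in practice
            raise ValueError("(I - A) is singular; model is not recursive") from err
        return B @ S @ B.T

    def implied_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Model-implied covariance over the observed variables."""
        C = self.total_covariance(theta)
        k = len(self.observed_vars)
        obs = [self.var_index[v] for v in self.observed_vars]
        return C[np.ix_(obs, obs)]

    def param_dict(self, theta: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        it = iter(theta)
        for p in self.parameters:
            out[p.name] = float(next(it)) if p.free else float(p.value)
        return out

    def __repr__(self) -> str:
        return (
            f"SemModel({len(self.observed_vars)} observed, {len(self.latent_vars)} latent, "
            f"{len(self.paths)} paths, {self.n_free} free parameters)"
        )


_RESID_RE = re.compile(r"^e(_\w+|\d+)$")


def parse_model_spec(text: str) -> SemModel:
    """Parse the plain-text model format into a validated :class:`SemModel`."""
    latents: list[str] = []
    raw_paths: list[tuple[str, str, float | None, float | None]] = []
    raw_covs: list[tuple[str, str, float | None]] = []
    fixed_var: dict[str, float] = {}
    mentioned: list[str] = []
    errors: list[str] = []

    def note(v: str) -> None:
        if v not in mentioned:
            mentioned.append(v)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            if ":" not in line:
                raise ValueError("expected '<keyword>: ...'")
            kw, body = (s.strip() for s in line.split(":", 1))
            if kw == "latent":
                for name in body.split():
                    if name not in latents:
                        latents.append(name)
            elif kw == "path":
                m = re.fullmatch(
                    r"(\S+)\s*->\s*(\S+?)(?:\s*=\s*(\S+))?(?:\s*~\s*(\S+))?", body
                )
                if not m:
                    raise ValueError(f"cannot parse path statement: {body!r}")
                src, tgt, fx, st = m.groups()
                raw_paths.append(
                    (src, tgt, float(fx) if fx else None, float(st) if st else None)
                )
                note(src)
                note(tgt)
            elif kw == "cov":
                m = re.fullmatch(r"(\S+)\s*<->\s*(\S+?)(?:\s*=\s*(\S+))?", body)
                if not m:
                    raise ValueError(f"cannot parse cov statement: {body!r}")
                a, b, fx = m.groups()
                raw_covs.append((a, b, float(fx) if fx else None))
                for v in (a, b):
                    if not _RESID_RE.match(v):
                        note(v)
            elif kw == "var":
                m = re.fullmatch(r"(\S+)\s*=\s*(\S+)", body)
                if not m:
                    raise ValueError(f"cannot parse var statement: {body!r}")
                fixed_var[m.group(1)] = float(m.group(2))
            else:
                raise ValueError(f"unknown keyword {kw!r}")
        except ValueError as err:
            errors.append(f"line {lineno}: {err}")
    if errors:
        raise ValueError("model spec errors:\n" + "\n".join(errors))
    if not raw_paths and not raw_covs:
        raise ValueError("empty model spec")

    observed = [v for v in mentioned if v not in latents]

    # Build a provisional model (ignoring residual tokens) to learn the
    # endogenous ordering, then resolve e-tokens in covariances.
    provisional = SemModel(
        observed_vars=observed,
        latent_vars=latents,
        paths=raw_paths,
        covariances=[
            (a, b, fx)
            for a, b, fx in raw_covs
            if not (_RESID_RE.match(a) or _RESID_RE.match(b))
        ],
        fixed_variances={
            v: x for v, x in fixed_var.items() if not _RESID_RE.match(v)
        },
    )

    def resolve(v: str) -> str:
        return provisional.resolve_residual(v) if _RESID_RE.match(v) else v

    covs = [(resolve(a), resolve(b), fx) for a, b, fx in raw_covs]
    fixed_resolved = {resolve(v): x for v, x in fixed_var.items()}
    return SemModel(
        observed_vars=observed,
        latent_vars=latents,
        paths=raw_paths,
        covariances=covs,
        fixed_variances=fixed_resolved,
    )
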