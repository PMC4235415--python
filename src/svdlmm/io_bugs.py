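"""Export the mixed model as BUGS-language model and data files.

The exported Gaussian model is the SVD-reparameterized family model:
the likelihood loops over families and individuals, the polygenic effect
enters as an inner product of a row of the loading matrix G with the
independent random-effect vector u over the family's offset slice, u is
a vector of univariate normals, fixed effects get dnorm(0, 0.001) priors
and the precisions get dgamma(1, 1).  The Bernoulli variant swaps the
likelihood line for a dbern with a logit link and drops tau.e.

Data are written in R-dump syntax (the format OpenBUGS and JAGS both
read), matrices serialized column-major with an explicit .Dim attribute
as R defines the format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .glmm import GLMMSpec, init_from_mle
from .lmm import LMMSpec, PriorSpec

__all__ = ["BugsBundle", "export_bugs", "parse_rdump"]

RESERVED = {
    "y", "u", "G", "offset", "mu", "p", "N", "n.fam",
    "tau.e", "tau.g", "sigma.g2", "sigma.e2", "herit",
}


@dataclass
class BugsBundle:
    model_text: str
    data_text: str
    inits_text: str

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "model.txt").write_text(self.model_text)
        (out / "data.txt").write_text(self.data_text)
        (out / "inits.txt").write_text(self.inits_text)


def _fmt_vector(v: np.ndarray) -> str:
    if np.issubdtype(np.asarray(v).dtype, np.integer):
        body = ", ".join(str(int(x)) for x in v)
    else:
        body = ", ".join(format(float(x), ".10g") for x in v)
    return f"c({body})"


def _rdump_entry(name: str, value) -> str:
    arr = np.asarray(value)
    if arr.ndim == 0:
        return f"`{name}` <- {format(arr.item(), '.10g')}"
    if arr.ndim == 1:
        return f"`{name}` <- {_fmt_vector(arr)}"
    # column-major flattening, as R's structure()/.Dim expects
    flat = arr.flatten(order="F")
    dims = ", ".join(str(s) for s in arr.shape)
    return f"`{name}` <- structure({_fmt_vector(flat)}, .Dim = c({dims}))"


def parse_rdump(text: str) -> dict[str, np.ndarray]:
    """Parse the R-dump subset written by :func:`export_bugs` back to arrays."""
    out: dict[str, np.ndarray] = {}
    pat = re.compile(
        r"`([^`]+)`\s*<-\s*(structure\()?\s*(c\(([^)]*)\)|[-\d.eE+]+)"
        r"(?:\s*,\s*\.Dim\s*=\s*c\(([^)]*)\)\s*\))?",
        re.S,
    )
    for m in pat.finditer(text):
        name, _, scalar_or_vec, vec_body, dim = m.groups()
        if vec_body is not None:
            vals = np.array([float(t) for t in vec_body.replace("\n", " ").split(",") if t.strip()])
        else:
            vals = np.array(float(scalar_or_vec))
        if dim:
            shape = tuple(int(float(t)) for t in dim.split(","))
            vals = vals.reshape(shape, order="F")
        out[name] = vals
    return out


def _coef_name(name: str) -> str:
    return "b0" if name.lower() == "intercept" else "b." + name


def _model_text(covariates: list[str], prior: PriorSpec, binary: bool) -> str:
    terms = ["b0"]
    for c in covariates:
        terms.append(f"b.{c}*{c}[j]")
    mean = " + ".join(terms)
    inprod = (
        "inprod(G[j, offset[i]:(offset[i+1]-1)], u[offset[i]:(offset[i+1]-1)])"
    )
    bp = format(prior.beta_precision, "g")
    ga, gb = format(prior.tau_shape, "g"), format(prior.tau_rate, "g")
    lines = ["model svd {", "   ## loop over families", "   for( i in 1:n.fam) {",
             "      ## loop over individuals within each family",
             "      for( j in offset[i]:(offset[i+1] - 1) ) {"]
    if binary:
        lines += [
            "         y[j] ~ dbern( p[j] )",
            f"         logit(p[j]) <- {mean} +",
            f"            {inprod}",
        ]
    else:
        lines += [
            "         y[j] ~ dnorm( mu[j], tau.e)",
            f"         mu[j] <- {mean} +",
            f"            {inprod}",
        ]
    lines += ["      }", "   }", "",
              "   ## model random effects as univariate normal",
              "   for( t in 1:N) { u[t] ~ dnorm( 0, tau.g) }", "",
              "   ## priors for fixed effects",
              f"   b0 ~ dnorm(0,{bp})"]
    for c in covariates:
        lines.append(f"   b.{c} ~ dnorm(0,{bp})")
    lines += ["", "   ## variance components"]
    if binary:
        lines += [f"   tau.g ~ dgamma({ga}, {gb})",
                  "   sigma.g2 <- 1/tau.g"]
    else:
        lines += [f"   tau.e ~ dgamma({ga}, {gb})",
                  f"   tau.g ~ dgamma({ga}, {gb})",
                  "   sigma.g2 <- 1/tau.g",
                  "   sigma.e2 <- 1/tau.e",
                  "   ## narrow-sense heritability",
                  "   herit <- (1/tau.g)/( 1/tau.g+1/tau.e)"]
    lines += ["}", ""]
    return "\n".join(lines)


def export_bugs(
    spec: LMMSpec | GLMMSpec,
    prior: PriorSpec | None = None,
    covariate_names: list[str] | None = None,
) -> BugsBundle:
    """Build model, data and initial-value files for OpenBUGS/JAGS.

    ``covariate_names`` names the non-intercept columns of X (defaults to
    the spec's names); they become data vectors and coefficients ``b.<name>``.
    The first column of X must be the intercept.
    """
    prior = prior or PriorSpec()
    binary = isinstance(spec, GLMMSpec)
    names = covariate_names if covariate_names is not None else spec.covariate_names[1:]
    if len(names) != spec.X.shape[1] - 1:
        raise ValueError("covariate_names must name every non-intercept column of X")
    clash = set(names) & RESERVED
    if clash:
        raise ValueError(f"covariate names collide with reserved symbols: {sorted(clash)}")
    if not np.allclose(spec.X[:, 0], 1.0):
        raise ValueError("first column of X must be the intercept")

    n = spec.off.n
    data = {
        "N": n,
        "n.fam": spec.off.n_fam,
        "offset": np.asarray(spec.off.offsets, dtype=int),
        "y": spec.y.astype(int) if binary else spec.y,
    }
    for j, name in enumerate(names, start=1):
        data[name] = spec.X[:, j]
    data["G"] = spec.G.assembled()
    data_text = "\n".join(_rdump_entry(k, v) for k, v in data.items()) + "\n"

    if binary:
        beta0 = init_from_mle(spec)
    else:
        beta0 = np.linalg.lstsq(spec.X, spec.y, rcond=None)[0]
    inits = {"b0": beta0[0]}
    for j, name in enumerate(names, start=1):
        inits[f"b.{name}"] = beta0[j]
    inits["u"] = np.zeros(n)
    inits["tau.g"] = 1.0
    if not binary:
        inits["tau.e"] = 1.0
    inits_text = "\n".join(_rdump_entry(k, v) for k, v in inits.items()) + "\n"

    return BugsBundle(
        model_text=_model_text(list(names), prior, binary),
        data_text=data_text,
        inits_text=inits_text,
    )
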