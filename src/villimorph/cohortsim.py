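"""Simulated randomised trial cohorts with masked 1:1:1:1 allocation.

Emulates the design of a double-blind placebo-controlled micronutrient
supplementation trial in adults with environmental enteropathy: four
allocation letters (two per arm) assigned 1:1:1:1 by a computer-generated
sequence, HIV status established after randomisation, one jejunal biopsy
after the supplementation period (plus an optional post-vaccination
biopsy in a subset), and orientation-failure attrition.

Morphometric measures are drawn from a Gaussian copula per
(arm, HIV-stratum): villous height (VH), crypt depth (CD) and villous
area (VA) have Gaussian marginals, while villous perimeter (VP) and
villous width (VW) are log-normal — so that a Shapiro–Wilk screen routes
the former to t-tests and the latter to rank tests, as in the trial this
emulates.  The letter→arm code map is sealed: only an explicit unblind
step after database lock can attach arm labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "ARMS",
    "MaskingError",
    "SealedCodeMap",
    "EffectSpec",
    "Cohort",
    "randomize",
    "simulate_cohort",
    "unblind",
    "paper_scenario",
    "null_scenario",
]

# column order follows the trial's correlation tables
MEASURES = ("VH", "CD", "VP_per100", "VW", "VA_per100")
# VP and VW are simulated log-normal (parameterized by median + log-SD);
# the remaining measures are Gaussian (mean + SD)
LOGNORMAL_MEASURES = ("VP_per100", "VW")
ARMS = ("MM", "placebo")
LETTERS = ("A", "B", "C", "D")


class MaskingError(RuntimeError):
    """Raised on any attempt to read arm identity before unblinding."""


class SealedCodeMap:
    """Letter→arm assignment held sealed until the database is locked.

    Mimics the code envelope held by the supplement manufacturer: the
    mapping cannot be read by item access; only :func:`unblind` (which
    verifies the cohort's database lock) opens it.
    """

    def __init__(self, mapping: dict[str, str]):
        arms = set(mapping.values())
        if not arms <= set(ARMS):
            raise ValueError(f"arms must be within {ARMS}, got {sorted(arms)}")
        self._mapping = dict(mapping)

    @property
    def letters(self) -> tuple[str, ...]:
        return tuple(sorted(self._mapping))

    def __getitem__(self, letter: str) -> str:
        raise MaskingError(
            "code map is sealed; use unblind(cohort, code_map) after locking"
        )

    def __repr__(self) -> str:
        return f"SealedCodeMap(letters={self.letters}, arms=<sealed>)"

    def _reveal(self, letter: str) -> str:
        if letter not in self._mapping:
            raise KeyError(f"code map has no entry for letter {letter!r}")
        return self._mapping[letter]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._mapping))

    @classmethod
    def from_json(cls, path: str | Path) -> "SealedCodeMap":
        return cls(json.loads(Path(path).read_text()))


def randomize(
    n: int, seed: int, letters: tuple[str, ...] = LETTERS
) -> tuple[list[str], SealedCodeMap]:
    """Allocate ``n`` participants to 4 letters in a 1:1:1:1 ratio.

    Letter counts are balanced within ±1 (the remainder letters are chosen
    at random).  Two letters are drawn to represent the active arm and two
    the placebo; the map is returned sealed.
    """
    if n < 1:
        raise ValueError(f"need at least 1 participant, got {n}")
    rng = np.random.default_rng(seed)
    base, rem = divmod(n, len(letters))
    pool = list(letters) * base + list(rng.choice(letters, size=rem, replace=False))
    allocation = list(rng.permutation(pool))
    active = rng.choice(letters, size=2, replace=False)
    mapping = {L: ("MM" if L in active else "placebo") for L in letters}
    return allocation, SealedCodeMap(mapping)


@dataclass(frozen=True)
class EffectSpec:
    """Statistical truth of a simulated cohort.

    ``means[(arm, hiv)][measure]`` gives the marginal centre of each
    measure: the mean for Gaussian measures, the *median* for the
    log-normal ones.  ``sds`` holds Gaussian SDs; ``log_sds`` holds the
    SDs of log(VP), log(VW).  ``corr[hiv]`` is the 5×5 correlation matrix
    of the underlying Gaussian copula in table order (VH, CD, VP, VW, VA).
    ``attrition_rate`` is the probability a biopsy fails the orientation
    screen (scalar or per-arm dict).  ``vaccination_effect`` shifts
    post-vaccination records additively (default: no effect).
    """

    means: dict
    sds: dict
    log_sds: dict
    corr: dict
    n_per_letter: int = 13
    hiv_prevalence: float = 15 / 38
    attrition_rate: float | dict = 0.0
    vaccination_effect: dict = field(default_factory=dict)
    post_biopsy_fraction: float = 14 / 38
    post_noise_sd_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.attrition_rate, dict):
            rates = list(self.attrition_rate.values())
        else:
            rates = [self.attrition_rate]
        for r in rates:
            if not 0 <= r < 1:
                raise ValueError(f"attrition_rate must be in [0, 1), got {r}")
        for hiv, R in self.corr.items():
            R = np.asarray(R, dtype=float)
            if R.shape != (len(MEASURES), len(MEASURES)):
                raise ValueError(f"corr[{hiv!r}] must be 5x5")
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValueError(
                    f"corr[{hiv!r}] must be symmetric with unit diagonal"
                )
            if np.linalg.eigvalsh(R).min() <= 0:
                raise ValueError(
                    f"corr[{hiv!r}] is not positive definite"
                )
        for m in MEASURES:
            sd = self.log_sds[m] if m in LOGNORMAL_MEASURES else self.sds[m]
            if sd <= 0:
                raise ValueError(f"SD for {m} must be > 0")

    def attrition_for(self, arm: str) -> float:
        if isinstance(self.attrition_rate, dict):
            return float(self.attrition_rate[arm])
        return float(self.attrition_rate)


@dataclass
class Cohort:
    """Simulated trial data plus masking state.

    ``data`` has one row per (participant, timepoint) with allocation
    letter but *no* arm column until :func:`unblind` is applied after
    :meth:`lock`.  ``audit`` records every masking-relevant event.
    """

    data: pd.DataFrame
    code_map: SealedCodeMap
    truth: EffectSpec
    locked: bool = False
    audit: list = field(default_factory=list)

    def lock(self) -> None:
        """Declare morphometry complete and the database locked."""
        self.locked = True
        self.audit.append("database locked")


def _draw_measures(
    rng: np.random.Generator, spec: EffectSpec, arm: str, hiv: str
) -> dict[str, float]:
    R = np.asarray(spec.corr[hiv], dtype=float)
    z = rng.multivariate_normal(np.zeros(len(MEASURES)), R, method="cholesky")
    out = {}
    for m, zi in zip(MEASURES, z):
        centre = spec.means[(arm, hiv)][m]
        if m in LOGNORMAL_MEASURES:
            out[m] = centre * float(np.exp(spec.log_sds[m] * zi))
        else:
            out[m] = centre + spec.sds[m] * float(zi)
    return out


def simulate_cohort(spec: EffectSpec) -> Cohort:
    """Simulate one masked cohort under ``spec``.

    Per-participant random streams are spawned deterministically from the
    master seed, so the cohort is reproducible and insensitive to
    vectorization details.  Biopsies failing orientation (attrition) keep
    their row with ``adequate=False`` and NaN measures, mirroring a
    CONSORT accounting of randomised vs analyzable participants.
    """
    n = spec.n_per_letter * len(LETTERS)
    allocation, code_map = randomize(n, seed=spec.seed)
    streams = np.random.SeedSequence(spec.seed).spawn(n + 1)
    rows = []
    for i, letter in enumerate(allocation):
        rng = np.random.default_rng(streams[i])
        arm = code_map._mapping[letter]  # generator-internal truth; masked in output
        hiv = "positive" if rng.random() < spec.hiv_prevalence else "negative"
        age = float(np.clip(rng.normal(39, 11), 18, 60))
        sex = "M" if rng.random() < 27 / 38 else "F"
        bmi = float(np.clip(rng.normal(23.8, 5.2), 15, 45))
        adequate = rng.random() >= spec.attrition_for(arm)
        measures = _draw_measures(rng, spec, arm, hiv)
        base = {
            "participant_id": f"P{i + 1:03d}",
            "letter": letter,
            "hiv": hiv,
            "age": round(age, 1),
            "sex": sex,
            "bmi": round(bmi, 1),
            "adequate": adequate,
        }
        pre = dict(base, timepoint="pre")
        for m in MEASURES:
            pre[m] = measures[m] if adequate else float("nan")
        rows.append(pre)
        if adequate and rng.random() < spec.post_biopsy_fraction:
            post = dict(base, timepoint="post")
            for m in MEASURES:
                shift = spec.vaccination_effect.get(m, 0.0)
                sd = (
                    spec.means[(arm, hiv)][m] * spec.log_sds[m]
                    if m in LOGNORMAL_MEASURES
                    else spec.sds[m]
                )
                noise = rng.normal(0.0, spec.post_noise_sd_fraction * sd)
                post[m] = max(1e-9, measures[m] + shift + noise)
            rows.append(post)
    cols = [
        "participant_id", "letter", "hiv", "age", "sex", "bmi",
        *MEASURES, "timepoint", "adequate",
    ]
    data = pd.DataFrame(rows)[cols]
    cohort = Cohort(data=data, code_map=code_map, truth=spec)
    cohort.audit.append(f"simulated cohort of {n} participants (seed {spec.seed})")
    return cohort


def unblind(cohort: Cohort, code_map: SealedCodeMap | None = None) -> Cohort:
    """Attach arm labels; only permitted once the database is locked."""
    if code_map is None:
        code_map = cohort.code_map
    if not cohort.locked:
        raise MaskingError(
            "refusing to unblind: database not locked (complete morphometry "
            "and call cohort.lock() first)"
        )
    letters = cohort.data["letter"].unique()
    arms = {L: code_map._reveal(L) for L in letters}
    data = cohort.data.copy()
    data["arm"] = data["letter"].map(arms)
    out = replace(cohort, data=data)
    out.audit = cohort.audit + [f"unblinded letters {sorted(letters)}"]
    return out


# ---------------------------------------------------------------------------
# default scenarios
# ---------------------------------------------------------------------------

# correlation structure of the five measures, by HIV stratum, in the
# order (VH, CD, VP, VW, VA); from observed jejunal morphometry in adults
# with environmental enteropathy
CORR_HIV_NEG = np.array(
    [
        [1.000, 0.180, 0.715, 0.424, 0.732],
        [0.180, 1.000, 0.180, -0.110, 0.170],
        [0.715, 0.180, 1.000, 0.140, 0.796],
        [0.424, -0.110, 0.140, 1.000, 0.426],
        [0.732, 0.170, 0.796, 0.426, 1.000],
    ]
)
CORR_HIV_POS = np.array(
    [
        [1.000, 0.254, 0.514, 0.182, 0.511],
        [0.254, 1.000, -0.236, 0.182, -0.154],
        [0.514, -0.236, 1.000, -0.268, 0.882],
        [0.182, 0.182, -0.268, 1.000, 0.093],
        [0.511, -0.154, 0.882, 0.093, 1.000],
    ]
)


def paper_scenario(seed: int = 0) -> EffectSpec:
    """Default effect structure of the emulated trial.

    HIV-negative strata reproduce the reported group contrasts (VH means
    293.3 v 236.6 μm with SD 36.3; VA means 27623 v 21650 μm²/100 μm;
    VP medians 355.0 v 273.7 μm/100 μm); CD centres follow the reported
    villous:crypt ratios (1.83 v 1.56).  HIV-positive strata are null
    (no supplement effect).  SDs not reported for a measure are set to
    values consistent with the reported confidence intervals.  Attrition
    uses the observed per-arm orientation-failure rates (8/26 and 6/26).
    """
    mm_neg = {
        "VH": 293.3, "CD": 160.3, "VP_per100": 355.0, "VW": 112.0,
        "VA_per100": 27623.0,
    }
    pl_neg = {
        "VH": 236.6, "CD": 151.7, "VP_per100": 273.7, "VW": 105.0,
        "VA_per100": 21650.0,
    }
    hiv_pos = {
        "VH": 230.0, "CD": 155.0, "VP_per100": 270.0, "VW": 105.0,
        "VA_per100": 21000.0,
    }
    return EffectSpec(
        means={
            ("MM", "negative"): mm_neg,
            ("placebo", "negative"): pl_neg,
            ("MM", "positive"): dict(hiv_pos),
            ("placebo", "positive"): dict(hiv_pos),
        },
        sds={"VH": 36.3, "CD": 30.0, "VA_per100": 5900.0},
        # log-SDs sized so VP and VW are visibly right-skewed (skewness
        # ~1.5), i.e. detectably non-normal at trial-size samples, as
        # observed for these measures in adults with enteropathy
        log_sds={"VP_per100": 0.45, "VW": 0.40},
        corr={"negative": CORR_HIV_NEG, "positive": CORR_HIV_POS},
        n_per_letter=13,
        attrition_rate={"MM": 8 / 26, "placebo": 6 / 26},
        seed=seed,
    )


def null_scenario(seed: int = 0, n_per_letter: int = 13) -> EffectSpec:
    """Zero-effect variant of :func:`paper_scenario` (type-I calibration)."""
    spec = paper_scenario(seed)
    pl_neg = spec.means[("placebo", "negative")]
    return replace(
        spec,
        means={key: dict(pl_neg) for key in spec.means},
        n_per_letter=n_per_letter,
        attrition_rate=0.0,
    )
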