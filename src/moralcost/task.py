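"""Stimulus construction and payoff rules for the bribe-taking task.

The task is a 2 x 2 within-subject design. A fictitious proposer has two
payoff options that always sum to CNY 100; the computer indicates one of
them. In the *Control* conduct the proposer honestly reports the indicated
option; in the *Bribe* conduct the proposer fraudulently reports the
non-indicated, more profitable option. The reported payoff is always the
larger of the two (56-96 CNY). The proposer offers the participant (the
power-holder) a share of the reported payoff; the participant accepts or
rejects. In the *Dyad* scenario an innocent third party earns 100 minus the
proposer's payoff of whichever option ends up applying; in the *Solo*
scenario no third party exists.

Accepting pays the power-holder the offer and the proposer the remainder of
the reported payoff. Rejecting pays both nothing; the third party (Dyad) is
then paid according to the computer-indicated option, which under Bribe is
the complement of the reported one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REPORTED_PAYOFFS: tuple[int, ...] = (56, 64, 72, 80, 88, 96)
OFFER_PROPORTIONS: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))
TOTAL_PIE = 100

SCENARIOS = ("Solo", "Dyad")
CONDUCTS = ("Control", "Bribe")
#: condition labels in canonical order: Solo/Dyad crossed with Control/Bribe
CONDITIONS = ("SC", "SB", "DC", "DB")

TRIAL_COLUMNS = [
    "subject_id",
    "run",
    "trial_index",
    "scenario",
    "conduct",
    "reported_payoff",
    "offer_amount",
    "offer_proportion",
]


@dataclass(frozen=True)
class Offer:
    """One proposer offer: a reported payoff and the share offered from it.

    ``offer_amount`` is the nearest integer (ties to even) of
    ``offer_proportion * reported_payoff``. Valid offers keep the proposer
    strictly better off than under the alternative option even after paying
    the offer: ``reported_payoff - offer_amount > 100 - reported_payoff``.
    """

    reported_payoff: int
    offer_proportion: float

    @property
    def offer_amount(self) -> int:
        return int(np.rint(self.offer_proportion * self.reported_payoff))

    @property
    def is_valid(self) -> bool:
        r, o = self.reported_payoff, self.offer_amount
        return r - o > TOTAL_PIE - r


@dataclass(frozen=True)
class Trial:
    """One decision problem faced by the power-holder."""

    scenario: str  # "Solo" | "Dyad"
    conduct: str  # "Control" | "Bribe"
    reported_payoff: int
    offer_amount: int

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.conduct not in CONDUCTS:
            raise ValueError(f"unknown conduct {self.conduct!r}")

    @property
    def q(self) -> int:
        """Bribe indicator: 1 under the Bribe conduct, else 0."""
        return 1 if self.conduct == "Bribe" else 0

    @property
    def condition(self) -> str:
        return self.scenario[0] + self.conduct[0]


@dataclass(frozen=True)
class PayoffTriple:
    """Payoffs implied by one choice: proposer, power-holder, third party.

    ``p_T`` is ``None`` on Solo trials, where no third party exists.
    """

    p_P: int
    p_PH: int
    p_T: int | None


def build_offer_set(
    reported_payoffs: Sequence[int] = REPORTED_PAYOFFS,
    proportions: Sequence[float] = OFFER_PROPORTIONS,
) -> list[Offer]:
    """Enumerate the constrained offer grid.

    Crosses the reported payoffs with the offer proportions and keeps only
    offers under which the proposer still earns strictly more than in the
    alternative option. With the default grid this yields exactly 36 offers,
    ordered by payoff then proportion.
    """
    offers = []
    for r in sorted(reported_payoffs):
        for p in sorted(proportions):
            offer = Offer(int(r), float(p))
            if offer.is_valid:
                offers.append(offer)
    return offers


def _check_offers_unique(offers: Sequence[Offer]) -> None:
    keys = [(o.reported_payoff, o.offer_proportion) for o in offers]
    if len(set(keys)) != len(keys):
        raise ValueError("offers contain duplicate (payoff, proportion) pairs")


def expand_design(
    offers: Sequence[Offer],
    n_subjects: int,
    seed: int,
) -> pd.DataFrame:
    """Expand offers into per-subject trial tables.

    Each subject sees every offer once in each of the four conditions
    (4 x len(offers) trials), split over two runs so that each offer appears
    exactly twice per run: the offer set is split at random into two halves,
    one half is paired with a random pair of conditions in run 1 (the other
    pair in run 2) and vice versa for the second half. Trial order within a
    run is shuffled. All randomization is driven by ``seed``.
    """
    if not offers:
        raise ValueError("offers must be nonempty")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError("seed must be an integer")
    _check_offers_unique(offers)
    if len(offers) % 2:
        raise ValueError("offer set must have even size to split across runs")

    rng = np.random.default_rng(seed)
    n_off = len(offers)
    rows: list[tuple] = []
    for s in range(1, n_subjects + 1):
        perm = rng.permutation(n_off)
        halves = (perm[: n_off // 2], perm[n_off // 2 :])
        cond_perm = rng.permutation(4)
        pair_a = [CONDITIONS[i] for i in cond_perm[:2]]
        pair_b = [CONDITIONS[i] for i in cond_perm[2:]]
        for run in (1, 2):
            run_rows = []
            # run 1: half 0 with pair_a, half 1 with pair_b; run 2 swaps pairs
            assignment = (
                [(halves[0], pair_a), (halves[1], pair_b)]
                if run == 1
                else [(halves[0], pair_b), (halves[1], pair_a)]
            )
            for idx, conds in assignment:
                for i in idx:
                    o = offers[i]
                    for cond in conds:
                        scenario = "Solo" if cond[0] == "S" else "Dyad"
                        conduct = "Control" if cond[1] == "C" else "Bribe"
                        run_rows.append(
                            (
                                f"sub{s:03d}",
                                run,
                                scenario,
                                conduct,
                                o.reported_payoff,
                                o.offer_amount,
                                o.offer_proportion,
                            )
                        )
            order = rng.permutation(len(run_rows))
            for t, j in enumerate(order, start=1):
                r = run_rows[j]
                rows.append((r[0], r[1], t) + r[2:])

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _as_trial(row) -> Trial:
    return Trial(
        scenario=row["scenario"],
        conduct=row["conduct"],
        reported_payoff=int(row["reported_payoff"]),
        offer_amount=int(row["offer_amount"]),
    )


def payoffs_for_choice(trial: Trial, choice: str) -> PayoffTriple:
    """Payoffs for all three roles under ``choice`` ("accept" | "reject").

    Accept: the power-holder earns the offer, the proposer the rest of the
    reported payoff, and the third party (Dyad) the complement of the
    reported payoff. Reject: proposer and power-holder earn nothing; the
    third party is paid per the computer-indicated option — identical to the
    reported one in Control, its complement in Bribe (where the reported
    option is the fraudulent, non-indicated one).
    """
    if choice not in ("accept", "reject"):
        raise ValueError(f"choice must be 'accept' or 'reject', got {choice!r}")
    dyad = trial.scenario == "Dyad"
    r = trial.reported_payoff
    if choice == "accept":
        p_t = (TOTAL_PIE - r) if dyad else None
        return PayoffTriple(p_P=r - trial.offer_amount, p_PH=trial.offer_amount, p_T=p_t)
    if dyad:
        p_t = r if trial.conduct == "Bribe" else TOTAL_PIE - r
    else:
        p_t = None
    return PayoffTriple(p_P=0, p_PH=0, p_T=p_t)


def trial_covariates(trial: Trial) -> dict[str, int]:
    """Expected-gain/-loss covariates used as parametric decision regressors.

    * ``expected_gain_PH``: the power-holder's gain if they accept (the offer).
    * ``expected_gain_P``: the proposer's gain if accepted.
    * ``expected_loss_T``: how much the third party stands to lose from an
      acceptance. Nonzero only on Dyad-Bribe trials, where acceptance moves
      the third party from the indicated payoff ``r`` to ``100 - r``:
      a loss of ``2 r - 100``.
    """
    r = trial.reported_payoff
    loss_t = 0
    if trial.scenario == "Dyad" and trial.conduct == "Bribe":
        loss_t = 2 * r - TOTAL_PIE
    return {
        "expected_gain_PH": trial.offer_amount,
        "expected_gain_P": r - trial.offer_amount,
        "expected_loss_T": loss_t,
    }


def validate_trial_table(df: pd.DataFrame) -> None:
    """Raise ValueError if a trial table violates the task invariants."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "trial_index"]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad_scen = set(df["scenario"]) - set(SCENARIOS)
    if bad_scen:
        raise ValueError(f"unknown scenario values: {sorted(bad_scen)}")
    bad_cond = set(df["conduct"]) - set(CONDUCTS)
    if bad_cond:
        raise ValueError(f"unknown conduct values: {sorted(bad_cond)}")
    r = df["reported_payoff"].to_numpy()
    o = df["offer_amount"].to_numpy()
    viol = ~(r - o > TOTAL_PIE - r)
    if viol.any():
        idx = np.flatnonzero(viol)[:5].tolist()
        raise ValueError(
            "offers violate the proposer-selfishness constraint "
            f"(reported - offer must exceed 100 - reported) at rows {idx}"
        )


def trials_from_frame(df: pd.DataFrame) -> Iterable[Trial]:
    """Iterate a trial table as Trial objects (row order preserved)."""
    for _, row in df.iterrows():
        yield _as_trial(row)
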