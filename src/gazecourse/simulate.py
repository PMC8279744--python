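"""Synthetic visual-world gaze and questionnaire data.

The generator emulates a look-and-listen experiment: on each trial a display
with a female and a male character (same occupation) and two objects is
previewed for 3 s, then a passive sentence plays whose critical verb conveys
a female-stereotypical, male-stereotypical, or neutral action and whose
critical noun names the agent. Gaze is modelled as a renewal process: gamma
dwell times, and at each fixation onset an AOI is drawn from a multinomial
whose probabilities follow the condition's anticipation profile — baseline
until the effect onset, then a logistic-shaped ramp of the target character's
log-odds toward the cell's asymptote, plus a referential ramp toward the
named agent after noun onset. Participant and item random effects scale the
anticipation effect on the log-odds scale, so a flat ("null") profile yields
genuinely exchangeable data.

Sampling is performed in a canonical category order (target character first),
so relabelling genders everywhere (profiles, items, agents) with the same
seed reproduces the identical dataset with female/male AOI labels swapped —
downstream log-ratio series are exactly negated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    ACTIONS,
    GENDERS,
    ConditionCell,
    ItemSet,
    PresentationList,
    Trial,
    latin_square_lists,
    randomize_presentation,
)

AOI_LABELS = ("female", "male", "object1", "object2", "elsewhere")


@dataclass(frozen=True)
class AnticipationProfile:
    """Pre-noun gaze preference of one occupation x action cell.

    ``onset_ms`` is relative to noun onset (negative = anticipatory); ``None``
    means the cell shows no anticipatory preference. ``target`` names the
    character the preference is directed at.
    """

    onset_ms: float | None
    asymptote: float = 0.65
    slope: float = 0.01  # 1/ms, steepness of the logistic ramp
    target: str = "female"


def default_profiles() -> dict[tuple[str, str], AnticipationProfile]:
    """Anticipation onsets by (occupation, action) cell.

    Female-stereotypical actions drive looks to the female character from
    1200 ms (female-stereotypical occupations) or 800 ms (male-stereotypical
    occupations) before the noun; male-stereotypical actions drive looks to
    the male character from 500 ms before the noun only in female-
    stereotypical occupation contexts; neutral actions and the male/male cell
    show no anticipation.
    """
    return {
        ("female", "female"): AnticipationProfile(-1200.0, target="female"),
        ("male", "female"): AnticipationProfile(-800.0, target="female"),
        ("female", "male"): AnticipationProfile(-500.0, target="male"),
        ("male", "male"): AnticipationProfile(None, target="male"),
        ("female", "neutral"): AnticipationProfile(None),
        ("male", "neutral"): AnticipationProfile(None),
    }


def null_profiles() -> dict[tuple[str, str], AnticipationProfile]:
    """Flat profiles: no anticipatory preference in any cell."""
    return {
        (occ, act): AnticipationProfile(None, target="female")
        for occ in GENDERS
        for act in ACTIONS
    }


@dataclass
class GeneratorParams:
    """Tunable parameters of the gaze simulator (times in ms)."""

    n_participants: int = 51
    dwell_mean: float = 250.0
    dwell_shape: float = 4.0
    #: baseline AOI probabilities over (female, male, object1, object2, elsewhere)
    baseline: tuple[float, ...] = (0.25, 0.25, 0.2, 0.2, 0.1)
    profiles: dict[tuple[str, str], AnticipationProfile] = field(default_factory=default_profiles)
    referential_onset: float = 200.0  # ms after noun onset (oculomotor delay)
    referential_asymptote: float = 0.75
    referential_slope: float = 0.01
    verb_onset_mean: float = 1719.26  # verb precedes noun by this, on average
    verb_onset_sd: float = 228.75
    participant_sd: float = 0.3  # random-effect SDs on the effect log-odds
    item_sd: float = 0.2
    preview_ms: float = 3000.0
    sentence_lead_ms: float = 500.0  # audio start -> verb onset
    post_noun_ms: float = 1500.0
    filler_accuracy: float = 0.91
    dropout: float = 0.0  # extra probability of a fixation landing elsewhere

    def validate(self) -> None:
        b = np.asarray(self.baseline, dtype=float)
        if b.shape != (5,) or (b < 0).any() or not math.isclose(b.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("baseline must be 5 non-negative probabilities summing to 1")
        if self.dwell_mean <= 0 or self.dwell_shape <= 0:
            raise ValueError("dwell parameters must be positive")
        for prof in self.profiles.values():
            if not 0.0 < prof.asymptote < 1.0:
                raise ValueError("asymptotes must lie in (0, 1)")
        if not 0.0 < self.referential_asymptote < 1.0:
            raise ValueError("referential asymptote must lie in (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def mirror_params(params: GeneratorParams) -> GeneratorParams:
    """Relabel genders everywhere in the generator parameters."""
    flip = {"female": "male", "male": "female", "neutral": "neutral"}
    profiles = {
        (flip[occ], flip[act]): replace(p, target=flip[p.target])
        for (occ, act), p in params.profiles.items()
    }
    b = params.baseline
    return replace(params, profiles=profiles, baseline=(b[1], b[0], b[2], b[3], b[4]))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _ramp(u: np.ndarray, slope: float) -> np.ndarray:
    """Logistic-shaped ramp: 0 for u <= 0, approaching 1 as u grows."""
    out = np.zeros_like(u, dtype=float)
    pos = u > 0
    out[pos] = 2.0 / (1.0 + np.exp(-slope * u[pos])) - 1.0
    return out


def _canonical_probs(
    t: np.ndarray,
    cell: ConditionCell,
    params: GeneratorParams,
    participant_effect: float,
    item_effect: float,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """AOI probabilities at times ``t`` (ms relative to noun onset), in the
    canonical order (target char, other char, object1, object2, elsewhere).

    Returns the (n, 5) probability matrix and the label tuple mapping the
    canonical columns to AOI names.
    """
    prof = params.profiles[(cell.occupation_stereotype, cell.action_stereotype)]
    tgt = prof.target if prof.onset_ms is not None else cell.agent_gender
    oth = "male" if tgt == "female" else "female"
    labels = (tgt, oth, "object1", "object2", "elsewhere")
    base = dict(zip(AOI_LABELS, params.baseline))
    w = np.tile([base[lab] for lab in labels], (len(t), 1))

    if prof.onset_ms is not None:
        delta = _logit(prof.asymptote) - _logit(base[tgt])
        amp = (delta + participant_effect + item_effect) * _ramp(t - prof.onset_ms, prof.slope)
        w[:, 0] *= np.exp(amp)

    # referential ramp toward the named agent after the noun
    agent_col = 0 if cell.agent_gender == labels[0] else 1
    delta_ref = _logit(params.referential_asymptote) - _logit(base[cell.agent_gender])
    w[:, agent_col] *= np.exp(delta_ref * _ramp(t - params.referential_onset, params.referential_slope))

    return w / w.sum(axis=1, keepdims=True), labels


def preference_probabilities(
    t,
    cell: ConditionCell,
    params: GeneratorParams,
    participant_effect: float = 0.0,
    item_effect: float = 0.0,
) -> np.ndarray:
    """AOI probabilities over (female, male, object1, object2, elsewhere) at
    time(s) ``t`` in ms relative to noun onset."""
    if (cell.occupation_stereotype, cell.action_stereotype) not in params.profiles:
        raise ValueError(f"no profile for cell {cell}")
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    probs, labels = _canonical_probs(tarr, cell, params, participant_effect, item_effect)
    order = [labels.index(lab) for lab in AOI_LABELS]
    out = probs[:, order]
    return out[0] if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class TrialTiming:
    verb_onset: float  # ms on the trial clock
    noun_onset: float
    t_end: float


def draw_timing(params: GeneratorParams, rng: np.random.Generator) -> TrialTiming:
    """Verb-to-noun interval from a truncated (> 0) normal."""
    while True:
        gap = rng.normal(params.verb_onset_mean, params.verb_onset_sd)
        if gap > 0:
            break
    verb = params.preview_ms + params.sentence_lead_ms
    noun = verb + gap
    return TrialTiming(verb_onset=verb, noun_onset=noun, t_end=noun + params.post_noun_ms)


def simulate_trial(
    cell: ConditionCell,
    timing: TrialTiming,
    params: GeneratorParams,
    rng: np.random.Generator,
    participant_effect: float = 0.0,
    item_effect: float = 0.0,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Simulate one trial's fixation sequence.

    Fixations abut (the renewal process never leaves the screen; "elsewhere"
    is itself an AOI outcome) and tile [0, t_end). In deterministic mode the
    dwell is fixed at 250 ms and the most probable AOI is always chosen —
    used for oracle checks only.
    """
    if deterministic:
        starts = np.arange(0.0, timing.t_end, 250.0)
        durs = np.full(starts.shape, 250.0)
    else:
        n_guess = int(timing.t_end / params.dwell_mean * 2) + 16
        durs = rng.gamma(params.dwell_shape, params.dwell_mean / params.dwell_shape, n_guess)
        while durs.sum() < timing.t_end:
            durs = np.concatenate(
                [durs, rng.gamma(params.dwell_shape, params.dwell_mean / params.dwell_shape, n_guess)]
            )
        ends_all = np.cumsum(durs)
        keep = np.searchsorted(ends_all, timing.t_end) + 1
        durs = durs[:keep]
        starts = np.concatenate([[0.0], ends_all[: keep - 1]])
    ends = np.minimum(starts + durs, timing.t_end)

    probs, labels = _canonical_probs(
        starts - timing.noun_onset, cell, params, participant_effect, item_effect
    )
    if deterministic:
        idx = probs.argmax(axis=1)
    else:
        cum = probs.cumsum(axis=1)
        u = rng.random(len(starts))
        idx = (u[:, None] > cum).sum(axis=1)
        if params.dropout > 0:
            idx[rng.random(len(starts)) < params.dropout] = 4
    return pd.DataFrame(
        {
            "fix_start": starts,
            "fix_end": ends,
            "aoi": [labels[i] for i in idx],
        }
    )


def simulate_experiment(
    item_set: ItemSet,
    lists: list[PresentationList],
    params: GeneratorParams,
    seed: int,
    simulate_filler_gaze: bool = False,
) -> dict[str, pd.DataFrame]:
    """Simulate a full experiment.

    Participants rotate through the presentation lists; each participant gets
    a pseudo-randomized trial order, per-trial verb/noun onsets, fixations on
    experimental trials (optionally also fillers) and a Bernoulli engagement
    response per filler.

    Returns ``{"fixations", "meta", "filler_responses"}`` data frames in the
    same dialect :mod:`gazecourse.fixio` consumes.
    """
    params.validate()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    order_seeds = np.random.SeedSequence(seed).generate_state(params.n_participants) % (2**31)

    u_p = rng.normal(0.0, params.participant_sd, params.n_participants)
    item_ids = [it.item_id for it in item_set.items]
    w_i = dict(zip(item_ids, rng.normal(0.0, params.item_sd, len(item_ids))))

    fix_rows, meta_rows, filler_rows = [], [], []
    for p in range(params.n_participants):
        pid = p + 1
        plist = lists[p % len(lists)]
        ordered = randomize_presentation(plist, int(order_seeds[p]))
        for trial in ordered.trials:
            timing = draw_timing(params, rng)
            meta_rows.append(
                {
                    "participant": pid,
                    "trial_id": trial.trial_id,
                    "position": trial.position,
                    "trial_type": trial.trial_type,
                    "list_id": plist.list_id,
                    "occupation_stereotype": trial.cell.occupation_stereotype if trial.cell else "",
                    "action_stereotype": trial.cell.action_stereotype if trial.cell else "",
                    "agent_gender": trial.cell.agent_gender if trial.cell else "",
                    "verb_onset": timing.verb_onset,
                    "noun_onset": timing.noun_onset,
                }
            )
            if trial.trial_type == "experimental":
                fx = simulate_trial(
                    trial.cell, timing, params, rng,
                    participant_effect=u_p[p],
                    item_effect=w_i[trial.trial_id],
                )
                fx.insert(0, "participant", pid)
                fx.insert(1, "trial_id", trial.trial_id)
                fix_rows.append(fx)
            else:
                if simulate_filler_gaze:
                    neutral_cell = ConditionCell("female", "neutral", "female")
                    fx = simulate_trial(neutral_cell, timing, params, rng)
                    fx.insert(0, "participant", pid)
                    fx.insert(1, "trial_id", trial.trial_id)
                    fix_rows.append(fx)
                filler_rows.append(
                    {
                        "participant": pid,
                        "trial_id": trial.trial_id,
                        "correct": int(rng.random() < params.filler_accuracy),
                    }
                )
    return {
        "fixations": pd.concat(fix_rows, ignore_index=True),
        "meta": pd.DataFrame(meta_rows),
        "filler_responses": pd.DataFrame(filler_rows),
    }


# ---------------------------------------------------------------------------
# Likert questionnaire simulation


@dataclass
class LikertGeneratorParams:
    """Single-common-factor Likert generator calibrated to a target alpha."""

    n_items: int = 29
    minimum: int = 1
    maximum: int = 7
    target_alpha: float = 0.89

    def validate(self) -> None:
        if not 0.0 <= self.target_alpha < 1.0:
            raise ValueError("target_alpha must lie in [0, 1)")
        if self.minimum >= self.maximum:
            raise ValueError("minimum must be < maximum")
        if self.n_items < 2:
            raise ValueError("n_items must be >= 2")


def _discretization_attenuation(n_levels: int) -> float:
    """Correlation between a standard normal score and its equal-probability
    ``n_levels``-category discretization; used to pre-compensate the factor
    loading so the *observed* item correlations hit the target alpha."""
    inner = stats.norm.ppf(np.arange(1, n_levels) / n_levels)
    # E[X ; lower < X < upper] = phi(lower) - phi(upper), with phi(+/-inf) = 0
    pdf_at = np.concatenate([[0.0], stats.norm.pdf(inner), [0.0]])
    mass = pdf_at[:-1] - pdf_at[1:]
    scores = np.arange(n_levels, dtype=float)
    cov = float((scores * mass).sum())
    var_s = (n_levels**2 - 1) / 12.0
    return cov / math.sqrt(var_s)


def simulate_likert(n_respondents: int, params: LikertGeneratorParams, seed: int) -> pd.DataFrame:
    """Simulate integer Likert responses with expected Cronbach's alpha near
    ``target_alpha``.

    Items load equally on one latent trait; the loading solves the
    Spearman-Brown relation for the target alpha, corrected for the
    attenuation induced by cutting the continuous responses at
    equal-probability thresholds.
    """
    params.validate()
    if n_respondents < 2:
        raise ValueError("n_respondents must be >= 2")
    rng = np.random.default_rng(seed)
    k = params.n_items
    a = params.target_alpha
    r_target = a / (k - a * (k - 1)) if a > 0 else 0.0
    n_levels = params.maximum - params.minimum + 1
    atten = _discretization_attenuation(n_levels)
    r_latent = min(r_target / atten**2, 0.999)
    lam = math.sqrt(r_latent)

    trait = rng.normal(size=(n_respondents, 1))
    noise = rng.normal(size=(n_respondents, k))
    latent = lam * trait + math.sqrt(1.0 - lam**2) * noise
    edges = stats.norm.ppf(np.arange(1, n_levels) / n_levels)
    responses = params.minimum + np.searchsorted(edges, latent).reshape(n_respondents, k)
    return pd.DataFrame(
        responses,
        columns=[f"item_{j + 1}" for j in range(k)],
        index=pd.RangeIndex(1, n_respondents + 1, name="participant"),
    )


def simulate_scale_battery(n_respondents: int, seed: int) -> dict[str, pd.DataFrame]:
    """The three explicit-attitude questionnaires with their published
    reliabilities: NGRO (29 items, 1-7, alpha 0.89), ASI-BS and ASI-HS
    (11 items each, 0-5, alphas 0.90 / 0.89)."""
    ss = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    return {
        "NGRO": simulate_likert(n_respondents, LikertGeneratorParams(29, 1, 7, 0.89), int(ss[0])),
        "ASI-BS": simulate_likert(n_respondents, LikertGeneratorParams(11, 0, 5, 0.90), int(ss[1])),
        "ASI-HS": simulate_likert(n_respondents, LikertGeneratorParams(11, 0, 5, 0.89), int(ss[2])),
    }


def default_design(n_occupations: int = 14, displays: int = 3, n_fillers: int = 28):
    """Convenience: the study's item set and six Latin-square lists."""
    from .design import build_item_set

    item_set = build_item_set(n_occupations, displays, n_fillers)
    return item_set, latin_square_lists(item_set)
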