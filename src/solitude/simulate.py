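"""Synthetic interview-cohort generator.

The restricted human interviews cannot be shipped, so every pipeline stage
is exercised on synthetic cohorts: Q/A-dialect transcripts paired with
loneliness / social-support scale scores, generated from a latent-variable
linear-Gaussian model with clipping.

Each participant draws a latent loneliness z ~ N(0,1).  Four response
characteristics are set as base + scale * (beta * z + noise_sd * eps) and
then *realized* in text sampled from slotted sentence pools:

* first-person-plural pronoun rate (beta negative: lonelier people say "we"
  less) — realized token-exactly by a whole-transcript quota over pronoun
  slots;
* negative-sentence rate (beta positive) — per-sentence Bernoulli choice
  among negative / positive / neutral sentence pools;
* words per response (beta negative) — per-response lognormal jitter
  (sigma = 0.45) around the participant mean, since real interview responses
  vary widely in length;
* relationship mentions in the important-relationships response (beta
  negative) — realized exactly, one lexicon word per relationship sentence.

The UCLA-3 loneliness score is round(40 + 10 z + noise) clipped to [20, 80],
so the >40 loneliness cutoff splits default cohorts roughly in half;
emotional/instrumental support are negatively and negative interactions
positively coupled to z.  Women draw higher communication frequencies and a
slightly lower none-understood rate than men, mirroring the gendered
contrasts the pipeline is meant to detect.  Everything is deterministic
given the seed.  No claim of discourse realism is made.
"""

from __future__ import annotations

import csv
import dataclasses
import functools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import word_tokenize
from .localization import load_templates
from .transcripts import Speaker, Transcript, Turn, write_transcript_file


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Effect sizes are standardized slopes on the latent loneliness variable;
    ``noise_sd`` is the SD of the per-participant trait noise added to each
    slope term, ``score_noise_sd`` the SD (scale points) of UCLA score noise.
    """

    n_participants: int = 97
    prop_women: float = 0.65
    beta_fpp_density: float = -0.5
    beta_negative_sentiment: float = 0.5
    beta_response_length: float = -0.5
    beta_relationship_count: float = -0.5
    noise_sd: float = 0.5
    score_noise_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 4:
            raise ValueError("need at least 4 participants")
        if not 0.0 <= self.prop_women <= 1.0:
            raise ValueError("prop_women must be in [0, 1]")
        if self.noise_sd <= 0 or self.score_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")


def strong_signal_config(seed: int = 0, n_participants: int = 100) -> GeneratorConfig:
    """|beta| = 1, noise_sd = 0.3: the strong-signal recovery condition."""
    return GeneratorConfig(
        n_participants=n_participants, beta_fpp_density=-1.0,
        beta_negative_sentiment=1.0, beta_response_length=-1.0,
        beta_relationship_count=-1.0, noise_sd=0.3, seed=seed)


def null_config(seed: int = 0, n_participants: int = 40) -> GeneratorConfig:
    """All betas zero: text carries no information about the scores."""
    return GeneratorConfig(
        n_participants=n_participants, beta_fpp_density=0.0,
        beta_negative_sentiment=0.0, beta_response_length=0.0,
        beta_relationship_count=0.0, seed=seed)


@dataclass
class SyntheticParticipant:
    participant_id: str
    gender: str  # "women" | "men"
    latent_loneliness: float
    ucla_score: int
    ess_e: float
    ess_i: float
    ess_ni: float
    ssi: float
    age: float
    education: float
    race: str
    marital: str
    transcript: Transcript
    ground_truth: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sentence pools.  Slots: {subj} we/I, {poss} our/my, {obj} us/me,
# {rel} relationship word.  Non-Q1/Q3 padding templates must not contain
# relationship-lexicon words; Q3 padding must not contain negation patterns.

_NEUTRAL = (
    "{subj} usually spend the morning reading the paper",
    "{subj} keep busy with small projects around the apartment",
    "{poss} days follow pretty much the same routine",
    "{subj} like to walk around the grounds when the weather is fine",
    "there is always something going on downstairs",
    "{subj} watch the news in the evening",
    "{poss} garden takes up a good part of the afternoon",
    "{subj} have lived here for quite a few years now",
    "the staff here keep {obj} informed about activities",
    "{subj} play cards on Tuesdays",
)

_POSITIVE = (
    "{subj} really enjoy the time {subj} spend together",
    "it makes {obj} happy to hear their voices",
    "{subj} feel grateful for the people around {obj}",
    "those visits are wonderful and {subj} cherish them",
    "{subj} have a good laugh about the old days",
    "that connection means a great deal to {obj}",
    "{subj} feel loved and cared for most of the time",
    "it is a joy when the whole group gets together",
)

_NEGATIVE = (
    "{subj} feel lonely in the evenings sometimes",
    "it has been hard since {subj} lost so many old companions",
    "{subj} worry that {subj} have become a burden",
    "some days feel empty and {subj} just sit by the window",
    "it is difficult to keep up and that makes {obj} sad",
    "{subj} feel isolated from the goings-on around here",
    "{subj} get tired and a little depressed in winter",
    "honestly {subj} struggle to reach out anymore",
)

_REL_IMPORTANT = (
    "{poss} {rel} lives close by and checks in on {obj}",
    "{poss} {rel} calls {obj} from back east",
    "{subj} are very close with {poss} {rel}",
    "{poss} {rel} comes over for dinner now and then",
    "she is {poss} {rel} and they visit when they can",
    "{poss} {rel} has always been there for {obj}",
)

_REL_UNDERSTOOD = (
    "{poss} {rel} really understands {obj}",
    "yes {poss} {rel} knows {obj} better than anyone",
    "{subj} can tell {poss} {rel} anything",
)

_NONE_UNDERSTOOD = (
    "no not really",
    "nobody truly gets what it is like at this age",
    "people are pleasant enough but no one understands {obj} fully",
)

_COPING = (
    "{subj} put on some music and try to keep {poss} mind occupied",
    "{subj} go down to the common room to be around people",
    "{subj} write letters or tidy up until the feeling passes",
    "sometimes {subj} just wait it out",
)

_COMMUNITY = (
    "{subj} do feel part of the community here",
    "{subj} go to the residents meetings most months",
    "the building has a real neighborhood feel to it",
    "{subj} keep to {poss} own floor mostly",
)

_MODE_SNIPPETS = {
    "phone": "on the phone",
    "email": "by email",
    "social_media": "on facebook",
    "video": "over video",
    "in_person": "in person",
}

#: Gendered communication-frequency phrase distributions (phrase, prob);
#: design means ~23.6 (women) and ~8.0 (men) contacts per month.
_FREQ_PHRASES_WOMEN = (("every day", 0.60), ("most days", 0.25),
                       ("once a week", 0.15))
_FREQ_PHRASES_MEN = (("every day", 0.15), ("most days", 0.05),
                     ("once a week", 0.45), ("couple times a month", 0.15),
                     ("once a month", 0.20))

_FREQ_PER_MONTH = {"every day": 30.0, "most days": 20.0, "once a week": 4.33,
                   "couple times a month": 2.0, "once a month": 1.0}

#: Probability a Q3 response reports being understood by no one.
NONE_UNDERSTOOD_RATE = {"women": 0.46, "men": 0.352}

_REL_CATEGORIES = (("children", 0.32), ("spouse", 0.18), ("sibling", 0.16),
                   ("friend", 0.16), ("grandchildren", 0.10),
                   ("parent", 0.04), ("other_family", 0.04))

_REL_WORDS = {
    "children": ("daughter", "son", "children"),
    "spouse": ("husband", "wife"),
    "sibling": ("sister", "brother"),
    "friend": ("friend", "neighbor"),
    "grandchildren": ("granddaughter", "grandson", "grandchildren"),
    "parent": ("mother", "father"),
    "other_family": ("niece", "nephew", "cousin"),
}

_FILLER_PREFIXES = ("Um,", "Uh,", "You know,", "Oh,")

_OPENING_Q = ("Thank you for taking the time to talk with me today. To "
              "start, can you tell me how long you have lived here and what "
              "a typical day looks like for you?")
_AGING_Q = "Moving on, what does successful aging mean to you?"
_TECH_Q = ("This next section is about technology. How comfortable are you "
           "with using new technology such as computers or smartphones?")
_CLOSING_Q = ("Those are all the questions I have. Is there anything else "
              "you would like to share?")

_AVG_TEMPLATE_WORDS = 9.0
_FILLER_PREFIX_PROB = 0.12


@dataclass
class _Sentence:
    template: str
    rel_word: Optional[str] = None
    kind: str = "neutral"  # neutral | positive | negative | rel | comm
    plural: bool = False

    def slot_count(self) -> int:
        return (self.template.count("{subj}") + self.template.count("{poss}")
                + self.template.count("{obj}"))

    def render(self) -> str:
        forms = ({"subj": "we", "poss": "our", "obj": "us"} if self.plural
                 else {"subj": "I", "poss": "my", "obj": "me"})
        text = self.template.format(rel=self.rel_word or "", **forms)
        text = " ".join(text.split())
        return text[0].upper() + text[1:] + "."

    def token_count(self) -> int:
        return len(word_tokenize(self.render()))


@functools.lru_cache(maxsize=1)
def _cached_templates():
    return tuple(load_templates())


def _choice(rng: np.random.Generator, pairs: Sequence[Tuple[str, float]]) -> str:
    items = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    return items[int(rng.choice(len(items), p=probs / probs.sum()))]


def _pick(rng: np.random.Generator, pool: Sequence[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _padding_sentence(rng: np.random.Generator, neg_rate: float) -> _Sentence:
    u = rng.random()
    if u < neg_rate:
        return _Sentence(_pick(rng, _NEGATIVE), kind="negative")
    if u < neg_rate + (1.0 - neg_rate) * 0.45:
        return _Sentence(_pick(rng, _POSITIVE), kind="positive")
    return _Sentence(_pick(rng, _NEUTRAL), kind="neutral")


def _n_sentences(rng: np.random.Generator, words_target: float) -> int:
    jitter = rng.lognormal(mean=-0.45 ** 2 / 2, sigma=0.45)
    return max(1, int(round(words_target * jitter / _AVG_TEMPLATE_WORDS)))


def _sample_rel_word(rng: np.random.Generator) -> str:
    category = _choice(rng, _REL_CATEGORIES)
    return _pick(rng, _REL_WORDS[category])


def generate_participant(
    config: GeneratorConfig,
    rng: np.random.Generator,
    index: int,
    gender: str,
) -> SyntheticParticipant:
    z = float(rng.normal())
    eps = rng.normal(size=4)
    fpp_rate = float(np.clip(
        0.05 + 0.02 * (config.beta_fpp_density * z
                       + config.noise_sd * eps[0]), 0.0, 0.15))
    neg_rate = float(np.clip(
        0.20 + 0.10 * (config.beta_negative_sentiment * z
                       + config.noise_sd * eps[1]), 0.0, 0.70))
    words_target = float(np.clip(
        45.0 + 12.0 * (config.beta_response_length * z
                       + config.noise_sd * eps[2]), 12.0, 120.0))
    rel_target = int(round(np.clip(
        4.0 + 1.5 * (config.beta_relationship_count * z
                     + config.noise_sd * eps[3]), 0.0, 10.0)))

    ucla = int(np.clip(round(40.0 + 10.0 * z
                             + config.score_noise_sd * rng.normal()), 20, 80))
    ess_e = float(np.clip(2.7 - 0.4 * z + 0.25 * rng.normal(), 0.0, 4.0))
    ess_i = float(np.clip(2.0 - 0.3 * z + 0.30 * rng.normal(), 0.0, 4.0))
    ess_ni = float(np.clip(0.7 + 0.3 * z + 0.25 * rng.normal(), 0.0, 3.0))
    ssi = float(np.clip(51.0 - 4.0 * z + 3.0 * rng.normal(), 20.0, 70.0))

    if gender == "women":
        age = float(np.clip(rng.normal(81.7, 6.9), 66, 94))
        education = float(np.clip(rng.normal(15.4, 2.4), 8, 20))
        marital = "not_single" if rng.random() < 0.35 else "single"
    else:
        age = float(np.clip(rng.normal(86.2, 5.9), 66, 94))
        education = float(np.clip(rng.normal(16.4, 2.2), 8, 20))
        marital = "not_single" if rng.random() < 0.53 else "single"
    race = "caucasian" if rng.random() < 0.92 else "other"

    templates = _cached_templates()
    question_texts: List[Tuple[str, str]] = [("opening", _OPENING_Q)]
    question_texts += [(t.label, t.template_text) for t in templates]
    question_texts += [("aging", _AGING_Q), ("tech", _TECH_Q),
                       ("closing", _CLOSING_Q)]

    # --- build sentence plans per response
    responses: Dict[str, List[_Sentence]] = {}
    none_understood = rng.random() < NONE_UNDERSTOOD_RATE[gender]
    understood_count = 0
    important_words: List[str] = []
    comm_freq_truth = 0.0
    for label, _q in question_texts:
        n_sent = _n_sentences(rng, words_target)
        plan: List[_Sentence] = []
        if label == "Q1":
            n_sent = max(n_sent, rel_target if rel_target else 1)
            for _ in range(rel_target):
                word = _sample_rel_word(rng)
                important_words.append(word)
                plan.append(_Sentence(_pick(rng, _REL_IMPORTANT),
                                      rel_word=word, kind="rel"))
            while len(plan) < n_sent:
                plan.append(_padding_sentence(rng, neg_rate))
        elif label == "Q3":
            if none_understood:
                plan.append(_Sentence(_pick(rng, _NONE_UNDERSTOOD),
                                      kind="negative"))
                while len(plan) < max(1, n_sent // 2):
                    plan.append(_Sentence(_pick(rng, _NEGATIVE),
                                          kind="negative"))
            else:
                understood_count = int(rng.integers(1, 4))
                for _ in range(understood_count):
                    plan.append(_Sentence(_pick(rng, _REL_UNDERSTOOD),
                                          rel_word=_sample_rel_word(rng),
                                          kind="rel"))
                while len(plan) < n_sent:
                    plan.append(_padding_sentence(rng, neg_rate))
        elif label == "Q4":
            phrases = (_FREQ_PHRASES_WOMEN if gender == "women"
                       else _FREQ_PHRASES_MEN)
            phrase = _choice(rng, phrases)
            comm_freq_truth = _FREQ_PER_MONTH[phrase]
            mode = _pick(rng, list(_MODE_SNIPPETS))
            plan.append(_Sentence(
                "{subj} talk with {poss} " + _sample_rel_word(rng) + " "
                + _MODE_SNIPPETS[mode] + " " + phrase, kind="comm"))
            if rng.random() < 0.35:
                lower = [p for p, f in _FREQ_PER_MONTH.items()
                         if f <= comm_freq_truth]
                second = _pick(rng, lower)
                mode2 = _pick(rng, list(_MODE_SNIPPETS))
                plan.append(_Sentence(
                    "{subj} also keep in touch " + _MODE_SNIPPETS[mode2]
                    + " " + second, kind="comm"))
            while len(plan) < n_sent:
                plan.append(_padding_sentence(rng, neg_rate))
        elif label == "Q5":
            plan.append(_Sentence(_pick(rng, _COMMUNITY)))
            while len(plan) < n_sent:
                plan.append(_padding_sentence(rng, neg_rate))
        elif label == "Q6":
            plan.append(_Sentence(_pick(rng, _COPING)))
            while len(plan) < n_sent:
                plan.append(_padding_sentence(rng, neg_rate))
        else:  # opening / Q2 / aging / tech / closing
            if label == "closing":
                n_sent = min(n_sent, 2)
            while len(plan) < n_sent:
                plan.append(_padding_sentence(rng, neg_rate))
        responses[label] = plan

    # --- realize the first-person-plural rate by whole-transcript quota
    all_sentences = [s for label, _ in question_texts
                     for s in responses[label]]
    total_tokens = sum(s.token_count() for s in all_sentences)
    quota = int(round(fpp_rate * total_tokens))
    sloted = [s for s in all_sentences if s.slot_count() > 0]
    order = rng.permutation(len(sloted))
    assigned = 0
    for idx in order:
        if assigned >= quota:
            break
        sloted[idx].plural = True
        assigned += sloted[idx].slot_count()

    # --- render turns
    turns: List[Turn] = []
    question_turn_index: Dict[str, int] = {}
    line = 1
    n_negative = sum(1 for s in all_sentences if s.kind == "negative")
    response_word_counts: List[int] = []
    for label, question in question_texts:
        turns.append(Turn(Speaker.INTERVIEWER, question, (line, line)))
        question_turn_index[label] = len(turns) - 1
        line += 1
        rendered = []
        for s in responses[label]:
            text = s.render()
            if rng.random() < _FILLER_PREFIX_PROB:
                prefix = _pick(rng, _FILLER_PREFIXES)
                text = prefix + " " + text[0].lower() + text[1:]
            rendered.append(text)
        response_word_counts.append(
            sum(len(word_tokenize(t)) for t in rendered))
        # split into 1-2 participant turns to exercise response concatenation
        if len(rendered) >= 3 and rng.random() < 0.3:
            cut = len(rendered) // 2
            chunks = [rendered[:cut], rendered[cut:]]
        else:
            chunks = [rendered]
        for chunk in chunks:
            turns.append(Turn(Speaker.PARTICIPANT, " ".join(chunk),
                              (line, line)))
            line += 1

    transcript = Transcript(participant_id=f"p{index:03d}", turns=turns)
    participant_tokens = word_tokenize(transcript.participant_text())
    fpp_words = {"we", "our", "us", "ours"}
    realized_fpp = (sum(1 for t in participant_tokens
                        if t.lower() in fpp_words) / len(participant_tokens))
    ground_truth = {
        "latent_loneliness": z,
        "target_fpp_rate": fpp_rate,
        "realized_fpp_density": realized_fpp,
        "target_negative_rate": neg_rate,
        "realized_negative_fraction": n_negative / len(all_sentences),
        "target_words_per_response": words_target,
        "realized_mean_words_per_response": float(
            np.mean(response_word_counts)),
        "relationship_mentions": rel_target,
        "understood_count": 0 if none_understood else understood_count,
        "none_understood": bool(none_understood),
        "comm_frequency_per_month": comm_freq_truth,
        "question_turn_index": {k: v for k, v in question_turn_index.items()
                                if k.startswith("Q")},
    }
    return SyntheticParticipant(
        participant_id=transcript.participant_id, gender=gender,
        latent_loneliness=z, ucla_score=ucla, ess_e=ess_e, ess_i=ess_i,
        ess_ni=ess_ni, ssi=ssi, age=age, education=education, race=race,
        marital=marital, transcript=transcript, ground_truth=ground_truth)


def generate_cohort(config: GeneratorConfig) -> List[SyntheticParticipant]:
    """Generate a full synthetic cohort, deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_women = int(round(config.n_participants * config.prop_women))
    genders = (["women"] * n_women
               + ["men"] * (config.n_participants - n_women))
    genders = [genders[i] for i in rng.permutation(len(genders))]
    return [generate_participant(config, rng, i, g)
            for i, g in enumerate(genders)]


def cohort_scores_frame(cohort: Sequence[SyntheticParticipant]):
    """Scores/demographics table for a cohort, indexed by participant id."""
    import pandas as pd

    return pd.DataFrame({
        "participant_id": [p.participant_id for p in cohort],
        "gender": [p.gender for p in cohort],
        "age": [p.age for p in cohort],
        "education": [p.education for p in cohort],
        "race": [p.race for p in cohort],
        "marital": [p.marital for p in cohort],
        "ucla": [p.ucla_score for p in cohort],
        "ess_e": [p.ess_e for p in cohort],
        "ess_i": [p.ess_i for p in cohort],
        "ess_ni": [p.ess_ni for p in cohort],
        "ssi": [p.ssi for p in cohort],
    }).set_index("participant_id")


def write_cohort(
    cohort: Sequence[SyntheticParticipant],
    directory: str | Path,
    config: GeneratorConfig | None = None,
) -> Dict[str, object]:
    """Write transcripts, the scores table and a ground-truth manifest.

    Layout: ``<dir>/transcripts/<id>.txt``, ``<dir>/scores.csv``,
    ``<dir>/manifest.json``.  Returns the manifest dict.
    """
    directory = Path(directory)
    tdir = directory / "transcripts"
    tdir.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        write_transcript_file(p.transcript, tdir)
    with open(directory / "scores.csv", "w", newline="",
              encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "gender", "age", "education",
                         "race", "marital", "ucla", "ess_e", "ess_i",
                         "ess_ni", "ssi"])
        for p in cohort:
            writer.writerow([p.participant_id, p.gender, f"{p.age:.1f}",
                             f"{p.education:.1f}", p.race, p.marital,
                             p.ucla_score, f"{p.ess_e:.2f}",
                             f"{p.ess_i:.2f}", f"{p.ess_ni:.2f}",
                             f"{p.ssi:.1f}"])
    manifest: Dict[str, object] = {
        "config": dataclasses.asdict(config) if config else None,
        "seed": config.seed if config else None,
        "participants": {p.participant_id: p.ground_truth for p in cohort},
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
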