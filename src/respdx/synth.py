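"""Synthetic sectioned-EHR generator with gold annotations.

Every downstream stage (entity recognition, normalization, diagnosis,
evaluation) is exercised on corpora produced here, so the generator makes
its generative structure fully explicit: ten respiratory disease classes,
each a :class:`DiseaseProfile` over a shared concept vocabulary spanning
all six entity categories, with

* class-specific *signature* concepts (high emission probability),
* *shared* symptoms (cough, fever, dyspnea, ...) emitted by many classes,
* *composite* findings (pulmonary nodule / lung mass) shared by lung
  cancer and tuberculosis — the presentation behind the two-step
  diagnostic path,
* *attribute-signal* concepts emitted by a pair of classes that differ
  mainly in how often the mention is negated, so assertion-aware features
  carry diagnostic signal that concept presence alone does not,
* comorbidity links (pulmonary infection records frequently carry COPD as
  a secondary diagnosis and emit its phenotypes, and vice versa).

Records are rendered through templates in two pseudo-language dialects:
``latin-pseudo`` (whitespace-delimited) and ``zh-pseudo`` (continuous
script, no delimiters), exercising both tokenizer contracts without
shipping real clinical text.  Rendering records a gold character span for
every mention, and sampling is fully determined by the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import diseases
from .ner import EntitySpan
from .normalize import AttributeRule, Lexicon, TermEntry

__all__ = [
    "SECTION_NAMES",
    "DiseaseProfile",
    "SynthConfig",
    "AnnotatedRecord",
    "build_default_profiles",
    "build_attribute_signal_profiles",
    "sample_record",
    "generate_corpus",
    "default_lexicon",
    "default_attribute_rules",
    "signature_match_label",
    "DEFAULT_CLASS_PRIORS",
]

SECTION_NAMES = (
    "chief_complaint",
    "history_of_present_illness",
    "physical_examination",
    "imaging_findings",
    "lab_findings",
)

#: Qualitative mirror of the corpus imbalance: largest prior ~0.20 (COPD),
#: smallest ~0.02 (pulmonary hypertension).
DEFAULT_CLASS_PRIORS = (
    0.199,  # COPD
    0.105,  # bronchial asthma
    0.090,  # bronchiectasis
    0.050,  # airway stenosis
    0.021,  # pulmonary hypertension
    0.140,  # lung cancer
    0.060,  # pulmonary tuberculosis
    0.170,  # pulmonary infectious diseases
    0.084,  # pleural disease
    0.081,  # interstitial lung disease
)

SIGNATURE_EMISSION = 0.85
PAIR_EMISSION = 0.80
COMPOSITE_EMISSION = 0.80
#: leak of signature concepts into the confusion partner at overlap=1
SIGNATURE_LEAK = 0.30
#: negation weights: P(negated) = negation_rate * weight
GENERIC_NEG_WEIGHT = 0.25
PAIR_NEG_WEIGHT_HI = 0.95
PAIR_NEG_WEIGHT_LO = 0.05


@dataclass(frozen=True)
class _Concept:
    concept_id: str
    category: str
    section: str
    surfaces: tuple[str, ...]


_SYLLABLES = (
    "ba be bi bo bu ca ce ci co cu da de di do du fa fe fi fo fu ga ge gi go "
    "la le li lo lu ma me mi mo mu na ne ni no nu pa pe pi po pu ra re ri ro "
    "ru sa se si so su ta te ti to tu va ve vi vo vu xa xe xi xo za ze zi zo"
).split()
_GENERATED_SURFACES: set[str] = set()


def _pseudo_synonyms(cid: str, n: int = 4) -> list[str]:
    """Deterministic pseudo-Latin synonym surfaces for one concept.

    Each concept's mentions are rendered through one of several lexically
    disjoint surface forms (curated plus generated), emulating the surface
    variability that terminology standardization collapses.
    """
    import zlib

    rng = np.random.default_rng(zlib.crc32(cid.encode()) % (2**31))
    out = []
    while len(out) < n:
        word = "".join(
            _SYLLABLES[i] for i in rng.integers(0, len(_SYLLABLES), size=4)
        )
        if word in _GENERATED_SURFACES:
            continue
        _GENERATED_SURFACES.add(word)
        out.append(word)
    return out


def _c(cid, cat, sec, *surfaces) -> _Concept:
    return _Concept(cid, cat, sec, tuple(surfaces) + tuple(_pseudo_synonyms(cid)))


# ---------------------------------------------------------------------------
# concept vocabulary (>= 60 concepts across all six entity categories)
# ---------------------------------------------------------------------------

_SHARED: list[tuple[_Concept, dict[int, float]]] = [
    (_c("cough", "symptom", "chief_complaint", "cough", "coughing", "tussis"),
     {0: 0.60, 1: 0.55, 2: 0.60, 3: 0.45, 6: 0.50, 7: 0.60, 9: 0.45}),
    (_c("fever", "symptom", "chief_complaint", "fever", "pyrexia", "febrile episodes"),
     {2: 0.35, 5: 0.30, 6: 0.55, 7: 0.65, 8: 0.35}),
    (_c("dyspnea", "symptom", "chief_complaint", "dyspnea", "breathlessness",
        "shortness of breath"),
     {0: 0.60, 1: 0.60, 3: 0.50, 4: 0.65, 8: 0.50, 9: 0.60}),
    (_c("chest_tightness", "symptom", "chief_complaint", "chest tightness",
        "thoracic oppression"),
     {0: 0.40, 1: 0.55, 4: 0.40, 5: 0.30, 7: 0.30}),
    (_c("fatigue", "symptom", "chief_complaint", "fatigue", "tiredness", "malaise"),
     {4: 0.40, 5: 0.45, 6: 0.50, 7: 0.35, 9: 0.40}),
    (_c("sputum", "symptom", "chief_complaint", "sputum production", "expectoration"),
     {0: 0.55, 2: 0.65, 3: 0.30, 6: 0.40, 7: 0.55}),
    (_c("wheeze", "symptom", "physical_examination", "wheezing", "wheezes heard"),
     {0: 0.50, 1: 0.65, 2: 0.30, 3: 0.45, 7: 0.30}),
    (_c("chest_pain", "symptom", "chief_complaint", "chest pain", "thoracic pain"),
     {4: 0.30, 5: 0.40, 6: 0.30, 7: 0.35, 8: 0.60}),
    (_c("appetite_loss", "symptom", "chief_complaint", "poor appetite", "anorexia"),
     {5: 0.45, 6: 0.45, 7: 0.30, 8: 0.30, 9: 0.30}),
    (_c("weight_loss", "symptom", "chief_complaint", "weight loss", "losing weight"),
     {5: 0.55, 6: 0.55, 7: 0.30, 8: 0.30, 9: 0.35}),
]

_SIGNATURES: dict[int, list[_Concept]] = {
    0: [
        _c("emphysema", "disease_name", "history_of_present_illness",
           "emphysema", "pulmonary emphysema"),
        _c("barrel_chest", "symptom", "physical_examination",
           "barrel chest", "barrel shaped thorax"),
        _c("reduced_fev1", "test", "lab_findings", "reduced fev1", "low fev1 ratio"),
        _c("hyperinflation", "image_finding", "imaging_findings",
           "hyperinflation", "hyperinflated lungs"),
        _c("tiotropium", "medication", "history_of_present_illness",
           "tiotropium", "tiotropium inhaler"),
    ],
    1: [
        _c("allergic_rhinitis", "disease_name", "history_of_present_illness",
           "allergic rhinitis", "seasonal rhinitis"),
        _c("episodic_wheeze", "symptom", "chief_complaint",
           "episodic wheeze", "nocturnal wheezing attacks"),
        _c("bronchodilator_response", "test", "lab_findings",
           "positive bronchodilator response", "reversible airflow obstruction"),
        _c("eosinophilia", "test", "lab_findings",
           "elevated eosinophils", "blood eosinophilia"),
        _c("salbutamol", "medication", "history_of_present_illness",
           "salbutamol", "albuterol"),
    ],
    2: [
        _c("chronic_purulent_sputum", "symptom", "chief_complaint",
           "chronic purulent sputum", "daily purulent expectoration"),
        _c("tram_track", "image_finding", "imaging_findings",
           "tram track opacities", "tram track sign"),
        _c("signet_ring", "image_finding", "imaging_findings",
           "signet ring sign", "dilated bronchi"),
        _c("pseudomonas", "test", "lab_findings",
           "pseudomonas culture", "sputum pseudomonas growth"),
        _c("chest_physiotherapy", "procedure", "history_of_present_illness",
           "chest physiotherapy", "airway clearance therapy"),
    ],
    3: [
        _c("stridor", "symptom", "physical_examination",
           "stridor", "inspiratory stridor"),
        _c("tracheal_narrowing", "image_finding", "imaging_findings",
           "tracheal narrowing", "subglottic narrowing"),
        _c("flow_volume_plateau", "test", "lab_findings",
           "flow volume plateau", "flattened flow volume loop"),
        _c("bronchoscopic_dilation", "procedure", "history_of_present_illness",
           "bronchoscopic dilation", "airway stenting"),
        _c("prior_tracheostomy", "procedure", "history_of_present_illness",
           "prior tracheostomy", "previous prolonged intubation"),
    ],
    4: [
        _c("loud_p2", "symptom", "physical_examination",
           "loud p2", "accentuated pulmonic sound"),
        _c("elevated_pasp", "test", "lab_findings",
           "elevated pasp", "raised pulmonary pressure on echo"),
        _c("rv_enlargement", "image_finding", "imaging_findings",
           "right ventricular enlargement", "rv dilation"),
        _c("peripheral_edema", "symptom", "physical_examination",
           "peripheral edema", "ankle swelling"),
        _c("sildenafil", "medication", "history_of_present_illness",
           "sildenafil", "sildenafil tablets"),
    ],
    5: [
        _c("spiculated_mass", "image_finding", "imaging_findings",
           "spiculated mass", "spiculated lesion"),
        _c("malignant_cytology", "test", "lab_findings",
           "positive cytology", "malignant cells on cytology"),
        _c("mediastinal_lymphadenopathy", "image_finding", "imaging_findings",
           "mediastinal lymphadenopathy", "enlarged mediastinal nodes"),
        _c("gefitinib", "medication", "history_of_present_illness",
           "gefitinib", "targeted therapy tablets"),
        _c("lobectomy", "procedure", "history_of_present_illness",
           "planned lobectomy", "lobectomy scheduled"),
    ],
    6: [
        _c("afb_smear", "test", "lab_findings",
           "positive afb smear", "acid fast bacilli seen"),
        _c("cavitary_lesion", "image_finding", "imaging_findings",
           "cavitary lesion", "cavitation"),
        _c("apical_infiltrate", "image_finding", "imaging_findings",
           "apical infiltrate", "upper lobe infiltrate"),
        _c("tuberculin", "test", "lab_findings",
           "positive tuberculin test", "strong tuberculin reaction"),
        _c("isoniazid", "medication", "history_of_present_illness",
           "isoniazid", "antituberculosis therapy"),
    ],
    7: [
        _c("elevated_crp", "test", "lab_findings",
           "elevated crp", "raised c reactive protein"),
        _c("leukocytosis", "test", "lab_findings",
           "leukocytosis", "elevated white cells"),
        _c("consolidation", "image_finding", "imaging_findings",
           "consolidation", "lobar consolidation"),
        _c("ceftriaxone", "medication", "history_of_present_illness",
           "ceftriaxone", "intravenous antibiotics"),
        _c("rigors", "symptom", "chief_complaint", "rigors", "shaking chills"),
    ],
    8: [
        _c("pleural_effusion", "image_finding", "imaging_findings",
           "pleural effusion", "fluid in pleural space"),
        _c("pleuritic_pain", "symptom", "chief_complaint",
           "pleuritic pain", "pain on deep inspiration"),
        _c("thoracentesis", "procedure", "history_of_present_illness",
           "thoracentesis", "pleural tap"),
        _c("exudative_fluid", "test", "lab_findings",
           "exudative fluid", "pleural exudate"),
        _c("reduced_breath_sounds", "symptom", "physical_examination",
           "decreased breath sounds", "diminished breath sounds"),
    ],
    9: [
        _c("velcro_crackles", "symptom", "physical_examination",
           "velcro crackles", "fine bibasilar crackles"),
        _c("reticular_opacities", "image_finding", "imaging_findings",
           "reticular opacities", "reticulation"),
        _c("ground_glass", "image_finding", "imaging_findings",
           "ground glass pattern", "ground glass opacities"),
        _c("reduced_dlco", "test", "lab_findings",
           "reduced dlco", "impaired diffusion capacity"),
        _c("pirfenidone", "medication", "history_of_present_illness",
           "pirfenidone", "antifibrotic therapy"),
    ],
}

_COMPOSITE: list[_Concept] = [
    _c("pulmonary_nodule", "image_finding", "imaging_findings",
       "pulmonary nodule", "lung nodule"),
    _c("lung_mass", "image_finding", "imaging_findings",
       "lung mass", "pulmonary mass"),
]

#: (concept, class where it is asserted, class where it is usually negated)
_PAIRS: list[tuple[_Concept, int, int]] = [
    (_c("hemoptysis", "symptom", "chief_complaint", "hemoptysis", "coughing blood"),
     2, 1),
    (_c("orthopnea", "symptom", "chief_complaint", "orthopnea",
        "breathless lying flat"), 4, 0),
    (_c("chills", "symptom", "chief_complaint", "chills", "shivering"), 7, 9),
    (_c("smoking_history", "disease_name", "history_of_present_illness",
        "heavy smoking history", "long term tobacco use"), 5, 6),
    (_c("clubbing", "symptom", "physical_examination", "digital clubbing",
        "finger clubbing"), 9, 8),
    (_c("hoarseness", "symptom", "chief_complaint", "hoarseness", "hoarse voice"),
     3, 5),
    (_c("night_sweats", "symptom", "chief_complaint", "night sweats",
        "nocturnal sweating"), 6, 7),
]

#: confusion partner receiving signature leak at overlap > 0; encodes the
#: infection-vs-COPD confusability phenomenon among others.
_CONFUSION_PARTNER = {0: 7, 7: 0, 5: 6, 6: 5, 1: 0, 2: 7, 3: 1, 4: 8, 8: 4, 9: 8}

# Polysemous surfaces: the same surface string denotes an image-finding
# concept when it occurs in the imaging section and a test concept in the
# lab section.  Entity category (from context) plus the category-keyed
# lexicon resolve the sense; representations that flatten the note into a
# bag of tokens cannot.  Each sense is its own concept with its own
# emission pattern.
_POLYSEMOUS: list[tuple[_Concept, _Concept]] = []
for _i in range(9):
    _shared_surfaces = tuple(_pseudo_synonyms(f"polyseme_{_i}", n=2))
    _POLYSEMOUS.append(
        (
            _Concept(f"poly{_i}_imaging", "image_finding", "imaging_findings",
                     _shared_surfaces),
            _Concept(f"poly{_i}_lab", "test", "lab_findings", _shared_surfaces),
        )
    )

ALL_CONCEPTS: list[_Concept] = (
    [c for c, _ in _SHARED]
    + [c for sigs in _SIGNATURES.values() for c in sigs]
    + _COMPOSITE
    + [c for c, _, _ in _PAIRS]
    + [c for pair in _POLYSEMOUS for c in pair]
)
_CONCEPT_BY_ID = {c.concept_id: c for c in ALL_CONCEPTS}
assert len(_CONCEPT_BY_ID) == len(ALL_CONCEPTS), "concept ids must be unique"


# ---------------------------------------------------------------------------
# zh-pseudo surface material: continuous script without delimiters
# ---------------------------------------------------------------------------

_ZH_SURFACE_BANK = "".join(
    dict.fromkeys(
        "咳嗽喘息痰热血胸闷痛肺气肿瘤核菌影结节空洞积液音管狭窄压心衰胀"
        "白球蛋培养引流切除素片叶段支扩张偏高阻塞浸润阴"
    )
)
_ZH_FILLER_BANK = ["患者自诉", "既往病程", "入院查体", "影像提示", "化验回报", "随访复查"]
_ZH_NEG_TRIGGERS = ("无", "否认")
_ZH_SEVERITY = {"mild": "轻度", "moderate": "中度", "severe": "重度"}
_ZH_TEMPORALITY = {"acute": "急性", "chronic": "慢性"}

_LATIN_NEG_TRIGGERS = ("no", "denies", "without")
_LATIN_SEVERITY = {"mild": "mild", "moderate": "moderate", "severe": "severe"}
_LATIN_TEMPORALITY = {"acute": "acute", "chronic": "chronic"}

_LATIN_PREFIXES = {
    "chief_complaint": ("reports", "presents with"),
    "history_of_present_illness": ("history of", "documented"),
    "physical_examination": ("exam shows", "auscultation reveals"),
    "imaging_findings": ("imaging shows", "radiograph demonstrates"),
    "lab_findings": ("labs show", "testing reveals"),
}
_ZH_PREFIXES = {
    "chief_complaint": ("患者自诉",),
    "history_of_present_illness": ("既往病程",),
    "physical_examination": ("入院查体",),
    "imaging_findings": ("影像提示",),
    "lab_findings": ("化验回报",),
}
_EMPTY_SECTION = {"latin-pseudo": "unremarkable .", "zh-pseudo": "未见异常。"}


def _zh_surface(global_index: int) -> str:
    bank = _ZH_SURFACE_BANK
    b = len(bank)
    i, j = divmod(global_index, b)
    return bank[i % b] + bank[j]


# keyed by the latin surface string alone so that polysemous surfaces stay
# polysemous in the continuous-script dialect
_ALL_SURFACES = list(dict.fromkeys(s for c in ALL_CONCEPTS for s in c.surfaces))
_ZH_SURFACE_OF = {s: _zh_surface(k) for k, s in enumerate(_ALL_SURFACES)}
assert len(set(_ZH_SURFACE_OF.values())) == len(_ZH_SURFACE_OF)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass
class DiseaseProfile:
    """Generative profile of one disease class.

    ``phenotype_emission`` maps concept id to emission probability;
    ``attribute_dist`` maps (concept id, attribute name) to a categorical
    distribution over attribute values.  For ``assertion`` the "negated"
    mass acts as a weight multiplied by the corpus-level negation rate.
    ``comorbidity`` maps a secondary class id to the probability that it
    co-occurs (and contributes additional phenotype emissions).
    """

    class_id: int
    phenotype_emission: dict[str, float] = field(default_factory=dict)
    attribute_dist: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    comorbidity: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        for cid, p in self.phenotype_emission.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"emission for {cid!r} outside [0,1]: {p}")
        for key, dist in self.attribute_dist.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"attribute distribution {key} sums to {total}")
            if any(not 0.0 <= v <= 1.0 for v in dist.values()):
                raise ValueError(f"attribute distribution {key} outside [0,1]")
        if self.comorbidity.get(self.class_id, 0.0) != 0.0:
            raise ValueError("comorbidity self-probability must be 0")
        for p in self.comorbidity.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("comorbidity probability outside [0,1]")

    def signature_concepts(self, threshold: float = 0.7) -> list[str]:
        return [c for c, p in self.phenotype_emission.items() if p >= threshold]


def _assertion_dist(weight: float) -> dict[str, float]:
    return {"present": 1.0 - weight, "negated": weight}


def build_default_profiles(overlap: float = 0.1) -> list[DiseaseProfile]:
    """The ten default disease profiles.

    ``overlap`` in [0,1] controls cross-class ambiguity: at 0 signature
    concepts are emitted by exactly one class and shared symptoms keep
    class-specific rates; at 1 shared-symptom emissions are identical
    across the classes that list them and signatures leak maximally into
    each class's confusion partner.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must be in [0,1], got {overlap}")
    profiles = [DiseaseProfile(class_id=k) for k in range(diseases.N_CLASSES)]

    for concept, bases in _SHARED:
        mean = sum(bases.values()) / len(bases)
        for k, base in bases.items():
            profiles[k].phenotype_emission[concept.concept_id] = (
                (1.0 - overlap) * base + overlap * mean
            )
            profiles[k].attribute_dist[(concept.concept_id, "assertion")] = (
                _assertion_dist(GENERIC_NEG_WEIGHT)
            )
            profiles[k].attribute_dist[(concept.concept_id, "severity")] = {
                "mild": 1 / 3, "moderate": 1 / 3, "severe": 1 / 3,
            }

    # temporality carries a mild class lean on cough/sputum
    for k in (0, 2, 9):
        for cid in ("cough", "sputum"):
            if cid in profiles[k].phenotype_emission:
                profiles[k].attribute_dist[(cid, "temporality")] = {
                    "chronic": 0.8, "acute": 0.2,
                }
    for cid in ("cough", "fever"):
        if cid in profiles[7].phenotype_emission:
            profiles[7].attribute_dist[(cid, "temporality")] = {
                "acute": 0.8, "chronic": 0.2,
            }

    for k, sigs in _SIGNATURES.items():
        partner = _CONFUSION_PARTNER[k]
        for concept in sigs:
            profiles[k].phenotype_emission[concept.concept_id] = SIGNATURE_EMISSION
            leak = overlap * SIGNATURE_LEAK
            if leak > 0.0:
                profiles[partner].phenotype_emission[concept.concept_id] = leak

    for concept in _COMPOSITE:
        for k in diseases.COMPOSITE_MEMBERS:
            profiles[k].phenotype_emission[concept.concept_id] = COMPOSITE_EMISSION

    for concept, present_class, negated_class in _PAIRS:
        for k, w in ((present_class, PAIR_NEG_WEIGHT_LO),
                     (negated_class, PAIR_NEG_WEIGHT_HI)):
            profiles[k].phenotype_emission[concept.concept_id] = PAIR_EMISSION
            profiles[k].attribute_dist[(concept.concept_id, "assertion")] = (
                _assertion_dist(w)
            )

    # comorbidity: infection records often carry COPD and vice versa
    profiles[diseases.PULMONARY_INFECTION].comorbidity[diseases.COPD] = 0.25
    profiles[diseases.COPD].comorbidity[diseases.PULMONARY_INFECTION] = 0.15

    for p in profiles:
        p.validate()
    return profiles


def build_attribute_signal_profiles(overlap: float = 0.1) -> list[DiseaseProfile]:
    """Probe corpus profiles where negation flips class meaning.

    The ten classes form five pairs.  Within a pair the two classes have
    *identical* emission profiles; the only systematic difference is the
    assertion distribution of the pair's discriminative concept (habitually
    asserted in one member, habitually negated in the other), so
    concept-presence features cannot separate pair members while
    assertion-aware features can.  Between pair groups the dominant
    evidence is carried by polysemous surfaces whose imaging sense points
    at one group and whose lab sense points at another: entity category
    plus lexicon lookup resolve the sense, while representations that
    flatten the note into a bag of tokens see the two senses conflated.
    Expected negation-trigger counts are balanced across all classes, so
    raw trigger frequencies carry no label signal either.  This is the
    corpus used to demonstrate the fine > coarse > bag-of-words ablation
    ordering; ``overlap`` is accepted for interface symmetry but the
    within-pair construction already fixes the ambiguity structure.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must be in [0,1], got {overlap}")
    pairing = {0: 4, 4: 0, 1: 2, 2: 1, 3: 5, 5: 3, 6: 7, 7: 6, 8: 9, 9: 8}
    groups = [(0, 4), (1, 2), (3, 5), (6, 7), (8, 9)]
    pair_concept = {
        (4, 0): "orthopnea", (1, 2): "hemoptysis", (3, 5): "hoarseness",
        (6, 7): "night_sweats", (9, 8): "clubbing",
    }
    profiles = [DiseaseProfile(class_id=k) for k in range(diseases.N_CLASSES)]

    # shared symptoms at their global mean rate in every class: clinical
    # flavour without label signal
    shared_ids = [c.concept_id for c, _ in _SHARED]
    for concept, bases in _SHARED:
        mean = sum(bases.values()) / len(bases)
        for k in range(diseases.N_CLASSES):
            profiles[k].phenotype_emission[concept.concept_id] = mean

    # faint symmetric signature flavour (identical within each pair)
    for k, sigs in _SIGNATURES.items():
        for concept in sigs:
            for j in (k, pairing[k]):
                profiles[j].phenotype_emission[concept.concept_id] = 0.08

    # polysemous surfaces: every class emits every polysemous surface at
    # the same rate, but which *sense* (imaging vs lab section) it takes
    # depends on the pair group, via a binary code over the groups.  Token
    # counts are therefore exactly label-independent -- a flattened
    # bag-of-tokens carries no signal from these mentions -- while the
    # category-resolved concepts encode the group code.  This is the main
    # between-group evidence.
    for i, (img_concept, lab_concept) in enumerate(_POLYSEMOUS):
        bit = i % 3
        for g_idx, members in enumerate(groups):
            sense = img_concept if (g_idx >> bit) & 1 else lab_concept
            for m in members:
                profiles[m].phenotype_emission[sense.concept_id] = 0.7

    # pair concepts: emitted by every class (presence uninformative); only
    # the focal pair carries the asymmetric assertion distribution
    pair_em, w_hi, w_lo = 0.9, 0.97, 0.03
    pair_ids = [cid for cid in pair_concept.values()]
    for cid in pair_ids:
        for k in range(diseases.N_CLASSES):
            profiles[k].phenotype_emission[cid] = pair_em
            profiles[k].attribute_dist[(cid, "assertion")] = _assertion_dist(
                GENERIC_NEG_WEIGHT
            )
    for (present_class, negated_class), cid in pair_concept.items():
        profiles[present_class].attribute_dist[(cid, "assertion")] = (
            _assertion_dist(w_lo)
        )
        profiles[negated_class].attribute_dist[(cid, "assertion")] = (
            _assertion_dist(w_hi)
        )

    # balance expected negated-mention counts across classes by tuning the
    # per-class generic negation weight on shared symptoms
    def expected_nonshared_neg(k: int) -> float:
        total = 0.0
        for cid in pair_ids:
            w = profiles[k].attribute_dist[(cid, "assertion")]["negated"]
            total += profiles[k].phenotype_emission[cid] * w
        return total

    sum_shared = sum(profiles[0].phenotype_emission[c] for c in shared_ids)
    target = max(expected_nonshared_neg(k) for k in range(diseases.N_CLASSES))
    target += GENERIC_NEG_WEIGHT * sum_shared
    for k in range(diseases.N_CLASSES):
        w_g = (target - expected_nonshared_neg(k)) / sum_shared
        w_g = min(1.0, max(0.0, w_g))
        for c in shared_ids:
            profiles[k].attribute_dist[(c, "assertion")] = _assertion_dist(w_g)

    for p in profiles:
        p.validate()
    return profiles


# ---------------------------------------------------------------------------
# record sampling and rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthConfig:
    n_records: int = 2000
    class_priors: tuple[float, ...] = DEFAULT_CLASS_PRIORS
    negation_rate: float = 0.6
    distractor_rate: float = 0.1
    template_language: str = "latin-pseudo"
    overlap: float = 0.1
    seed: int = 20190401

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class_priors must sum to 1")
        if not 0.0 <= self.negation_rate <= 1.0:
            raise ValueError("negation_rate must be in [0,1]")
        if not 0.0 <= self.distractor_rate <= 1.0:
            raise ValueError("distractor_rate must be in [0,1]")
        if self.template_language not in ("latin-pseudo", "zh-pseudo"):
            raise ValueError(f"unknown template_language {self.template_language!r}")

    @property
    def tokenizer_dialect(self) -> str:
        return "whitespace" if self.template_language == "latin-pseudo" else "character"


@dataclass
class AnnotatedRecord:
    """One synthetic EHR: sectioned text, gold spans, gold labels."""

    record_id: str
    sections: dict[str, str]
    gold_spans: list[EntitySpan]
    primary_label: int
    secondary_labels: list[int] = field(default_factory=list)

    def validate(self) -> None:
        for s in self.gold_spans:
            text = self.sections[s.section]
            if not (0 <= s.start < s.end <= len(text)):
                raise ValueError(f"span {s} outside its section text")
            if text[s.start : s.end] != s.surface:
                raise ValueError(f"span surface mismatch for {s}")
        if self.primary_label in self.secondary_labels:
            raise ValueError("primary label repeated among secondary labels")


@dataclass
class _Mention:
    concept: _Concept
    attributes: dict[str, str]


def _sample_mention_attributes(
    profile: DiseaseProfile, concept: _Concept, config: SynthConfig, rng
) -> dict[str, str]:
    attrs: dict[str, str] = {}
    adist = profile.attribute_dist
    neg_weight = adist.get((concept.concept_id, "assertion"), {}).get("negated", 0.0)
    if rng.random() < config.negation_rate * neg_weight:
        attrs["assertion"] = "negated"
    sev = adist.get((concept.concept_id, "severity"))
    if sev is not None and rng.random() < 0.35:
        values, probs = zip(*sorted(sev.items()))
        attrs["severity"] = values[rng.choice(len(values), p=np.array(probs))]
    tmp = adist.get((concept.concept_id, "temporality"))
    if tmp is not None and rng.random() < 0.4:
        values, probs = zip(*sorted(tmp.items()))
        attrs["temporality"] = values[rng.choice(len(values), p=np.array(probs))]
    return attrs


def _render_sentence(
    mention: _Mention, config: SynthConfig, rng
) -> tuple[str, int, int, str]:
    """Render one mention; returns (sentence, surface start, end, surface)."""
    concept = mention.concept
    zh = config.template_language == "zh-pseudo"
    surface_latin = concept.surfaces[rng.choice(len(concept.surfaces))]
    surface = (
        _ZH_SURFACE_OF[surface_latin] if zh else surface_latin
    )
    prefixes = (_ZH_PREFIXES if zh else _LATIN_PREFIXES)[concept.section]
    parts = [prefixes[rng.choice(len(prefixes))]]
    if mention.attributes.get("assertion") == "negated":
        trig = _ZH_NEG_TRIGGERS if zh else _LATIN_NEG_TRIGGERS
        parts.append(trig[rng.choice(len(trig))])
    sev = mention.attributes.get("severity")
    if sev:
        parts.append((_ZH_SEVERITY if zh else _LATIN_SEVERITY)[sev])
    tmp = mention.attributes.get("temporality")
    if tmp:
        parts.append((_ZH_TEMPORALITY if zh else _LATIN_TEMPORALITY)[tmp])
    if zh:
        head = "".join(parts)
        sentence = head + surface + "。"
        start = len(head)
    else:
        head = " ".join(parts)
        sentence = head + " " + surface + " ."
        start = len(head) + 1
    return sentence, start, start + len(surface), surface


def sample_record(
    profiles: Sequence[DiseaseProfile],
    config: SynthConfig,
    rng: np.random.Generator,
    record_id: str = "rec-000000",
) -> AnnotatedRecord:
    """Draw one annotated record from the generative model."""
    if not profiles:
        raise ValueError("profiles must be non-empty")
    primary = int(rng.choice(len(profiles), p=np.array(config.class_priors)))
    profile = profiles[primary]
    secondary: list[int] = []
    for other, p in sorted(profile.comorbidity.items()):
        if other != primary and rng.random() < p:
            secondary.append(other)
            break

    emitted: dict[str, _Mention] = {}
    for cid, p in sorted(profile.phenotype_emission.items()):
        if rng.random() < p:
            concept = _CONCEPT_BY_ID[cid]
            emitted[cid] = _Mention(
                concept, _sample_mention_attributes(profile, concept, config, rng)
            )
    for sec_label in secondary:
        sec_profile = profiles[sec_label]
        for cid, p in sorted(sec_profile.phenotype_emission.items()):
            if cid in emitted:
                continue
            if rng.random() < 0.6 * p:
                concept = _CONCEPT_BY_ID[cid]
                emitted[cid] = _Mention(
                    concept,
                    _sample_mention_attributes(sec_profile, concept, config, rng),
                )
    if not emitted:
        cid = sorted(profile.signature_concepts() or profile.phenotype_emission)[0]
        emitted[cid] = _Mention(_CONCEPT_BY_ID[cid], {})

    n_distract = int(rng.binomial(2, config.distractor_rate))
    if n_distract:
        candidates = [c.concept_id for c in ALL_CONCEPTS if c.concept_id not in emitted]
        for cid in rng.choice(candidates, size=min(n_distract, len(candidates)),
                              replace=False):
            concept = _CONCEPT_BY_ID[cid]
            emitted[cid] = _Mention(
                concept, _sample_mention_attributes(profile, concept, config, rng)
            )

    # render mentions into their sections, shuffling sentence order
    per_section: dict[str, list[_Mention]] = {s: [] for s in SECTION_NAMES}
    for m in emitted.values():
        per_section[m.concept.section].append(m)
    sections: dict[str, str] = {}
    spans: list[EntitySpan] = []
    sep = "" if config.template_language == "zh-pseudo" else " "
    for section in SECTION_NAMES:
        mentions = per_section[section]
        order = rng.permutation(len(mentions))
        text_parts: list[str] = []
        offset = 0
        for idx in order:
            sentence, s0, s1, surface = _render_sentence(mentions[idx], config, rng)
            spans.append(
                EntitySpan(
                    section=section,
                    start=offset + s0,
                    end=offset + s1,
                    category=mentions[idx].concept.category,
                    surface=surface,
                    attributes=tuple(sorted(mentions[idx].attributes.items())),
                )
            )
            text_parts.append(sentence)
            offset += len(sentence) + len(sep)
        sections[section] = (
            sep.join(text_parts) if text_parts
            else _EMPTY_SECTION[config.template_language]
        )
    spans.sort(key=lambda s: (SECTION_NAMES.index(s.section), s.start))
    record = AnnotatedRecord(
        record_id=record_id,
        sections=sections,
        gold_spans=spans,
        primary_label=primary,
        secondary_labels=secondary,
    )
    record.validate()
    return record


def generate_corpus(
    config: SynthConfig,
    profiles: Sequence[DiseaseProfile] | None = None,
) -> tuple[list[AnnotatedRecord], list[AnnotatedRecord]]:
    """Sample a corpus and split it 80/20, stratified by primary label.

    Identical configs produce byte-identical corpora.
    """
    if config.n_records < 10:
        raise ValueError("n_records must be >= 10 for a stratified 8:2 split")
    profiles = list(profiles) if profiles is not None else build_default_profiles(
        config.overlap
    )
    rng = np.random.default_rng(config.seed)
    records = [
        sample_record(profiles, config, rng, record_id=f"rec-{i:06d}")
        for i in range(config.n_records)
    ]
    by_class: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.primary_label, []).append(i)
    for label, idx in sorted(by_class.items()):
        if len(idx) < 2:
            raise ValueError(
                f"class {label} has {len(idx)} record(s); stratified split needs >= 2"
            )
    # largest-remainder allocation: per-class test counts deviate from the
    # 4:1 target by < 1 record while the overall test size is exactly 20%
    labels = sorted(by_class)
    quota = {c: 0.2 * len(by_class[c]) for c in labels}
    alloc = {c: int(np.floor(quota[c])) for c in labels}
    n_test_total = int(round(0.2 * config.n_records))
    remainders = sorted(
        labels, key=lambda c: (-(quota[c] - alloc[c]), c)
    )
    i = 0
    while sum(alloc.values()) < n_test_total and i < 10 * len(labels) + 10:
        c = remainders[i % len(labels)]
        if alloc[c] < len(by_class[c]) - 1:
            alloc[c] += 1
        i += 1
    for c in labels:  # every class keeps >= 1 record on each side
        alloc[c] = min(max(alloc[c], 1), len(by_class[c]) - 1)
    test_idx: set[int] = set()
    for label in labels:
        idx = by_class[label]
        perm = rng.permutation(len(idx))
        test_idx.update(idx[k] for k in perm[: alloc[label]])
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# derived resources
# ---------------------------------------------------------------------------


def default_lexicon(template_language: str = "latin-pseudo") -> Lexicon:
    """Terminology lexicon covering every surface the renderer can emit."""
    zh = template_language == "zh-pseudo"
    entries = []
    for concept in ALL_CONCEPTS:
        for s in concept.surfaces:
            surface = _ZH_SURFACE_OF[s] if zh else s
            entries.append(
                TermEntry(surface, concept.category, concept.concept_id,
                          concept.surfaces[0])
            )
    return Lexicon(entries)


def default_attribute_rules(template_language: str = "latin-pseudo") -> list[AttributeRule]:
    """Attachment rules matching the renderer's trigger inventory."""
    zh = template_language == "zh-pseudo"
    rules = [
        AttributeRule(
            "assertion", "negated",
            _ZH_NEG_TRIGGERS if zh else _LATIN_NEG_TRIGGERS,
            direction="pre", scope_window=8 if zh else 3,
        )
    ]
    sev = _ZH_SEVERITY if zh else _LATIN_SEVERITY
    for value, trig in sev.items():
        rules.append(AttributeRule("severity", value, (trig,), "pre", 6 if zh else 2))
    tmp = _ZH_TEMPORALITY if zh else _LATIN_TEMPORALITY
    for value, trig in tmp.items():
        rules.append(
            AttributeRule("temporality", value, (trig,), "pre", 6 if zh else 2)
        )
    return rules


def signature_match_label(
    record: AnnotatedRecord,
    profiles: Sequence[DiseaseProfile],
    lexicon: Lexicon | None = None,
) -> int:
    """Trivial reference classifier: the class whose signature concepts best
    match the record's gold concepts (ties to the lower class id).

    Used as a corpus learnability probe, not as a model.
    """
    lexicon = lexicon or default_lexicon()
    concepts = set()
    for s in record.gold_spans:
        cid = lexicon.lookup(s.surface, s.category)
        if cid is not None:
            concepts.add(cid)
    best, best_score = 0, -1.0
    for p in profiles:
        sigs = set(p.signature_concepts())
        if not sigs:
            continue
        score = len(concepts & sigs) / len(sigs)
        if score > best_score:
            best, best_score = p.class_id, score
    return best
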