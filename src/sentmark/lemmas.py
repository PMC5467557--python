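"""Small rule-based English lemmatizer.

Covers the inflection classes that matter for matching scientific prose:
noun plurals and verb -s/-ed/-ing forms, plus an irregular table for the
verbs common in methods/results sections.  Deterministic and dependency-free;
a caller needing richer morphology can inject its own ``lemma`` callable
wherever one is accepted.
"""

from __future__ import annotations

__all__ = ["lemma"]

_IRREGULAR_VERBS = {
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "being": "be", "has": "have", "had": "have", "having": "have",
    "did": "do", "done": "do", "does": "do",
    "found": "find", "showed": "show", "shown": "show", "saw": "see", "seen": "see",
    "took": "take", "taken": "take", "gave": "give", "given": "give",
    "underwent": "undergo", "undergone": "undergo",
    "made": "make", "chose": "choose", "chosen": "choose",
    "began": "begin", "begun": "begin", "led": "lead", "met": "meet",
    "ran": "run", "held": "hold", "kept": "keep", "built": "build",
    "sought": "seek", "brought": "bring", "thought": "think",
    "wrote": "write", "written": "write", "drew": "draw", "drawn": "draw",
    "grew": "grow", "grown": "grow", "knew": "know", "known": "know",
    "came": "come", "went": "go", "got": "get", "gotten": "get",
    "said": "say", "felt": "feel", "left": "leave", "meant": "mean",
    "put": "put", "set": "set", "read": "read", "cut": "cut",
}

_IRREGULAR_NOUNS = {
    "children": "child", "men": "man", "women": "woman", "people": "person",
    "criteria": "criterion", "phenomena": "phenomenon", "data": "datum",
    "analyses": "analysis", "hypotheses": "hypothesis", "diagnoses": "diagnosis",
    "indices": "index", "matrices": "matrix", "stimuli": "stimulus",
    "nuclei": "nucleus", "foci": "focus", "cortices": "cortex",
    "series": "series", "species": "species",
}

_VOWELS = set("aeiou")

# words ending -ss, -us, -is that a bare s-strip would mangle
_KEEP_S = ("ss", "us", "is")


def _is_vowel(ch: str) -> bool:
    return ch in _VOWELS or ch == "y"


def _fix_stem(stem: str) -> str:
    """Normalize a stem left after stripping -ed/-ing.

    Undoubles a doubled final consonant (scanned -> scan) and restores the
    silent e after a single-vowel + single-consonant ending (measur ->
    measure, us -> use) or after v/c/u, which English words do not end in.
    """
    if (
        len(stem) >= 3
        and stem[-1] == stem[-2]
        and not _is_vowel(stem[-1])
        and stem[-1] not in "lsz"  # "fell", "miss", "buzz" keep the double
    ):
        return stem[:-1]
    if stem.endswith(("v", "c", "u")):
        return stem + "e"
    if len(stem) >= 5 and stem.endswith(("er", "en", "on", "om")):
        return stem  # unstressed final syllable: register, happen, reckon
    if stem.endswith("s"):
        # collapse/parse keep a silent e after a consonant; short stems like
        # "us" do too; longer vowel+s stems (focus, bias) do not
        if not _is_vowel(stem[-2]) or len(stem) <= 3:
            return stem + "e"
        return stem
    if (
        len(stem) >= 2
        and not _is_vowel(stem[-1])
        and stem[-1] not in "wxy"
        and _is_vowel(stem[-2])
        and (len(stem) == 2 or not _is_vowel(stem[-3]) or stem[-4:-2] == "qu")
    ):
        return stem + "e"  # CVC ending: requir -> require; reveal (VVC) stays
    return stem


def _verb_lemma(word: str) -> str:
    if word in _IRREGULAR_VERBS:
        return _IRREGULAR_VERBS[word]
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"  # studied -> study
    if word.endswith("eed"):
        return word[:-1]  # agreed -> agree
    if word.endswith("ed") and len(word) > 3:
        return _fix_stem(word[:-2])
    if word.endswith("ying") and len(word) > 5:
        return word[:-4] + "y"  # studying -> study
    if word.endswith("ing") and len(word) > 4:
        return _fix_stem(word[:-3])
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "sses", "xes", "zes")):
        return word[:-2]
    if word.endswith("s") and not word.endswith(_KEEP_S) and len(word) > 3:
        return word[:-1]
    return word


def _noun_lemma(word: str) -> str:
    if word in _IRREGULAR_NOUNS:
        return _IRREGULAR_NOUNS[word]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "sses", "xes", "zes")):
        return word[:-2]
    if word.endswith("s") and not word.endswith(_KEEP_S) and len(word) > 3:
        return word[:-1]
    return word


def lemma(word: str, pos: str = "n") -> str:
    """Lemmatize ``word`` with a coarse POS hint, ``'v'`` (verb) or ``'n'``.

    Input is lower-cased first; output is always lower case.
    """
    word = word.lower()
    if not word:
        return word
    if pos.startswith("v"):
        return _verb_lemma(word)
    return _noun_lemma(word)
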