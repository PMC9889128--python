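"""Fixed English stop-word list, version-pinned with the package.

A deliberately small, closed-class list: determiners, prepositions,
conjunctions, pronouns, auxiliaries and a handful of high-frequency
adverbs.  Content words are never stopped — for a relevance filter over
scientific abstracts the informative vocabulary is open-class.
"""

STOPWORDS_VERSION = "1"

STOPWORDS = frozenset(
    """
    a an the this that these those some any each no
    and or but nor so yet both either neither
    of in on at by for with without from to into onto over under
    between among through during before after above below about against
    as is are was were be been being am
    has have had having do does did done
    will would shall should can could may might must
    it its itself they them their themselves he him his she her hers
    we us our ourselves you your yours i me my
    not only also very too more most less least than then there here
    when where which who whom whose what why how while if because
    such other another same own per via
    """.split()
)
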