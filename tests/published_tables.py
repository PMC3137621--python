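"""Published per-cell values of the capuchin forearm study tables.

Frozen expected values shared by the fixture and acceptance tests: for every
(muscle, comparison species) cell the published CAI and similarity-band word,
and for every (group, comparison species) the published GCAI at its printed
precision.  HS/S/SS/D abbreviate the four band words.
"""

HS = "highly similar"
S = "similar"
SS = "somewhat similar"
D = "dissimilar"

#: (muscle, species) -> (published CAI, published band word)
MUSCLE_CELLS = {
    # superficial flexors
    ("flexor carpi ulnaris", "Homo"): (0.0, HS),
    ("flexor carpi ulnaris", "Pan"): (0.0, HS),
    ("flexor carpi ulnaris", "Papio"): (0.0, HS),
    ("palmaris longus", "Homo"): (0.425, SS),
    ("palmaris longus", "Pan"): (0.0, HS),
    ("palmaris longus", "Papio"): (0.0, HS),
    ("flexor carpi radialis", "Homo"): (0.125, S),
    ("flexor carpi radialis", "Pan"): (0.250, SS),
    ("flexor carpi radialis", "Papio"): (0.0, HS),
    ("flexor digitorum superficialis", "Homo"): (0.375, SS),
    ("flexor digitorum superficialis", "Pan"): (0.375, SS),
    ("flexor digitorum superficialis", "Papio"): (0.0, HS),
    ("pronator teres", "Homo"): (0.375, SS),
    ("pronator teres", "Pan"): (0.375, SS),
    ("pronator teres", "Papio"): (0.0, HS),
    # deep flexors
    ("pronator quadratus", "Homo"): (0.375, SS),
    ("pronator quadratus", "Pan"): (0.0, HS),
    ("pronator quadratus", "Papio"): (0.0, HS),
    ("flexor digitorum profundus", "Homo"): (0.0, HS),
    ("flexor digitorum profundus", "Pan"): (0.0625, S),
    ("flexor digitorum profundus", "Papio"): (1.0, D),
    ("flexor pollicis longus", "Homo"): (0.125, S),
    ("flexor pollicis longus", "Pan"): (0.0, HS),
    ("flexor pollicis longus", "Papio"): (0.250, SS),
    # extensors
    ("brachioradialis", "Homo"): (0.0, HS),
    ("brachioradialis", "Pan"): (0.0, HS),
    ("brachioradialis", "Papio"): (0.0, HS),
    ("extensor carpi radialis longus", "Homo"): (0.22, SS),
    ("extensor carpi radialis longus", "Pan"): (0.0, HS),
    ("extensor carpi radialis longus", "Papio"): (0.0, HS),
    ("extensor carpi radialis brevis", "Homo"): (0.0, HS),
    ("extensor carpi radialis brevis", "Pan"): (0.0, HS),
    ("extensor carpi radialis brevis", "Papio"): (0.0, HS),
    ("supinator", "Homo"): (0.0, HS),
    ("supinator", "Pan"): (0.0, HS),
    ("supinator", "Papio"): (0.0, HS),
    ("extensor digitorum communis", "Homo"): (0.22, SS),
    ("extensor digitorum communis", "Pan"): (0.0, HS),
    ("extensor digitorum communis", "Papio"): (0.0, HS),
    ("extensor digiti quinti proprius", "Homo"): (0.22, SS),
    ("extensor digiti quinti proprius", "Pan"): (0.22, SS),
    ("extensor digiti quinti proprius", "Papio"): (0.0, HS),
    ("extensor carpi ulnaris", "Homo"): (0.0, HS),
    ("extensor carpi ulnaris", "Pan"): (0.0, HS),
    ("extensor carpi ulnaris", "Papio"): (0.0, HS),
    ("extensor pollicis longus", "Homo"): (0.250, SS),
    ("extensor pollicis longus", "Pan"): (0.22, SS),
    ("extensor pollicis longus", "Papio"): (0.22, SS),
    ("extensor indicis propius", "Homo"): (0.22, SS),
    ("extensor indicis propius", "Pan"): (0.0, HS),
    ("extensor indicis propius", "Papio"): (0.0, HS),
    ("abductor pollicis longus", "Homo"): (0.0, HS),
    ("abductor pollicis longus", "Pan"): (0.250, SS),
    ("abductor pollicis longus", "Papio"): (0.250, SS),
    ("extensor pollicis brevis", "Homo"): (0.250, SS),
    ("extensor pollicis brevis", "Pan"): (0.0, HS),
    ("extensor pollicis brevis", "Papio"): (1.0, D),
}

#: (group, species) -> (published GCAI, printed decimals, published band word)
GROUP_CELLS = {
    ("superficial_flexor", "Homo"): (0.26, 2, SS),
    ("superficial_flexor", "Pan"): (0.20, 2, S),
    ("superficial_flexor", "Papio"): (0.0, 2, HS),
    ("deep_flexor", "Homo"): (0.167, 3, S),
    ("deep_flexor", "Pan"): (0.02, 2, S),
    ("deep_flexor", "Papio"): (0.417, 3, SS),
    ("extensor", "Homo"): (0.125, 3, S),
    ("extensor", "Pan"): (0.063, 3, S),
    ("extensor", "Papio"): (0.134, 3, S),
}

#: Cells whose CAI is derivable from a stated RF encoding (never overridden).
DERIVABLE_NONZERO = {
    ("flexor carpi radialis", "Homo"): 0.125,
    ("flexor carpi radialis", "Pan"): 0.250,
    ("pronator quadratus", "Homo"): 0.375,
    ("flexor pollicis longus", "Papio"): 0.250,
    ("flexor digitorum profundus", "Papio"): 1.0,
    ("extensor pollicis brevis", "Papio"): 1.0,
}
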