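;; SYNTHETIC reference AQP panel — constructed stand-in for a
;; hand-annotated panel of characterized aquaporins; see
;; mipkit.panel_builder for the construction. 3 members per
;; subfamily (PIP, TIP, NIP, SIP).
>refNIP-1 subfamily=NIP species=synthetic
GRSNAKATNGGIQNYAEEDKLVIFVVFFLLLIMAVLILIIAKQGNHHTKPRTSNQVLIML
FLILLWVIVVVILIIARNGDSQAGTGERTNPANRQDGSSTAGGDRAMVALVVMLAAMLIM
FIFLLLQGGEDSSKSLERRHKSDTQEQQKAMVVLIVLAFVVVMVIFAVAVFGEQLEHKRG
NQENDVAIVVVIMLAVFAAVIVILILGDNPAHAARSGGTNRFGKKTHRGPSENYSLMLLI
MIIVIALLFVLMLLIATKQSAAQYAITTRSYSSKK
>refNIP-2 subfamily=NIP species=synthetic
GGSNKKATNGGIQNYAEEDKAVIFVVVFLLLIMAVLILIIAKQGNHHTKPRTSNQVLIML
FLILLWVIVFVILLIARNGDSGAGTGERTNPANRQDGSRTAGGDRAMVALVVIVLAMLIM
FIFLVLQGHEDSSKSLEKHSRQDTQEQQEAMVVLLVLVFVVVMVIFAVAVFGEDLEHKRS
RQENDVAIVVVIMLAVFAIVIVILILGDNPAHAARTGGTNRFGKKTHEGPSENYSLMLVI
MIIVIILLIILMLLIATKQSAAQYAITTDSYSYKK
>refNIP-3 subfamily=NIP species=synthetic
NGSNAKATNGGIQNYAEEDKLVIFIVFFLLLIMAVLILIIAKQGNHHTKPRTSNQVLIMV
FLILLWVIVVVIILIARNGDSGAGTGERTNPANRQDGSRTAGGDRMMVALVVILLAMLIM
FIFIVLTGGEDSSKSLERHQKSDTQEQQEAMLVLIVLAFVVVMVIFAVAVFGEGLEHKRR
RQENDVAIVVVIMLAVFAAVIVILVLGDNPAHAARTGGTNRFGKKTHRSPSEQYSLMLVI
MIIVMIVLFILMLLIATKQSAAQYAITTDSYSYKE
>refPIP-1 subfamily=PIP species=synthetic
DGESKRAHNQGPSEARSSNNLVLAAAILLILLLAFLLLILLQGADFHAKFDYEQKAIAAL
AMLLVFFLFLFLIIAVKGDGRERGNKRSHNPADGKSYDKTASGEYFAIMVVVVLMLFLAV
LIFIIIGAYLSSEGDPARRHSGDADGGNYALVLVIIVLIVMVVFVMVIFVFSRAGGESET
GGKHSMFIILVIVIIHLVLVLVFLLLTYNPATTGRTENSSYESNHGSSKNDANYKIVILM
IMILLLLILLIIFAVISSTSGAGFSWAGRKKQSNQ
>refPIP-2 subfamily=PIP species=synthetic
DGESKRGHNAGPSEARSSNTAVLAAAVLLILLLLFLLLILLQGTDFHTKFAYEQYAIAML
AMLLVFLLFLFLIIAFKGDGRERGNKRSHNPADGKSYAKTATGYYFAIMVVVVMALLLAI
IIFIIIGAYLSSEGDPARRHSTDADGGNSNLALFIIVLIVILVMVFVIIVFSRAGGESST
GGKGSMFIILVILIIHLVMVLVFLLLTYNPATTGRTENSSYEGNHGYSRNDAYYKIVILM
LMILLLMILLIIFAVASNTSGAGFSWAGRKKQNNQ
>refPIP-3 subfamily=PIP species=synthetic
DGESKRAHNAGPSEARSSNTAVLIAFILLILLLLFLLLILLQGTDFHAKFDYEQYAIAMI
AMLLVFLLFAFLIIAFKGDGRERGNKRSHNPADGDSGAKTASGYYFAIMVVVVLMLLLAV
LLFIIIGAYLSSEYDPARRHSKDADGGNSALVLFIIVLIVMLVFVMVIIVFSRAGGESQT
GGKGSMFIILVIVIIHLVLVLVFLALTANPATTGRTENSSYEGNHGYARNDANYKIVILM
IMILLLLILLIIFAVISRTSGAGFSWAGRKKGSNQ
>refSIP-1 subfamily=SIP species=synthetic
TTKKQEKGGNYDDERYNSGTIALMLFIILIVVAFFIVVLLVAKATKEDQSRARDSAMLVL
AFAILLFIAALILLAVGYERKGSARSTNRNPAAGNQRTAESGHDDMVILFVVIAIILIFL
VLMLLVGQKNGNKQQEHNSDQSGHTKKKTTMIIAIVLFFFIFLMIFAAFIVEKNSKYRSD
EAGRSMFVAIMAALVVILVFVMFLVMSANPAKPSNSSTTDGIKEHKRKGDDYSSYILLVA
FILILLVLALVIFLLVYSNAGAGYKWEKTTGDGDA
>refSIP-2 subfamily=SIP species=synthetic
TTKGQEKGSNYDDERYNSGTIALILFIILIVVAIAVVVLLIAKANKEGQSSARDNAMLVL
ALAILLFIAVLILLAVHKERKQSATSTNRNPAAGNQRTAESGHDDMVIIFVVIAVILIFL
VIMLLVGQKNGNKKAEHNSRQSGNTKKKTQMLIAIILFFFIFLMIFAAAIVKKNSKYRDD
EAGRSMFVAIMAILVVILVFVMFLVMSANPAKPSNSSTTGGIKEDKRKGDDYSSYILLVA
FILILLVLLLVIFLLVYSGAGAGYSWEKTTGDGDA
>refSIP-3 subfamily=SIP species=synthetic
TTKYQEKGSNYDDERYNSGTIALILFIILIVVALAVVVLLVAKNNKEDQSSARDNAMLVV
ALAILLFIAALILLMVGKERKGSATSTNDNPAAGNQRTAEQQHDDLIILFVVIAIILIFF
VIMLLVGQKNTNKKEEHNSDQSGHTKKKTTMVIAIILFFFLFLMIFAAIIVKKNSKYRSD
EAGRSMFVAIMAIIVVILVFVAFLVMSANPAKPSNSSTTDGIKEHKRKGDDYSSYILLVL
FILILLVLLLVIFLLVYSNAGAGYKWEKTTGDGDA
>refTIP-1 subfamily=TIP species=synthetic
RRTSNRQAKGGGRGTGGSGEVLAILLIILIVIVFLILLALIRYGHVDQGFNDTDYLLFIL
IFVIVHFIIILLVIFFGKKKTRSHNEHKDNPAKDAGGGTYKHGTGLFIALIVLFLIAIIA
LVALLIGKDIEKRQAQDRANTRQTNHGQQGVLMLAMVMIIMFVIFIVIMFFNGNFYGQGE
GSNRRLAFLFILVAVILIVAILVVIISKNPASARVRDGSNQTDDDVGGKPRAYRNLVIVA
LIILLAILVLLMLIAFHEDSDAHYQWAEGDTATRE
>refTIP-2 subfamily=TIP species=synthetic
SDTSNRQAKGGGRGTGYSGEVLAILLILLIVIVIAILLALIRYGDVSQGFNDTDYLLFIL
IFVIVHFIIILLVIFFGKKKTRSHGEHKDNPAKDAGGGTYKHGTGLLIIFIVLFLIAIIA
LVALLIGKDIEKEQAQDNANSRQTNHGQNGVLMLAMVMIIMFVIFIAVMFFNANFTGQGE
GENRRLIFLFILVVVIFIVAFLVVIISKNPASARVRDGKNQTDDDVGGKPRAYRNLVIVA
LIILLAILVLLMLIVFHEDSDAHYQWAEGDKATRE
>refTIP-3 subfamily=TIP species=synthetic
RDTKNRQAKGGGRGTGGSGEVLLILLILLIVIVILALLALIRYGHVSQGFNDTDNLMFIL
FFIIVHFIIILLVLFFGKKKTRSQNEHKDNPAKDAGGDTYKHTTGLFIALIVLFLIAIIA
LVLLLIGKDIEKRQAQDRANTRQTNHGQNGVLMLAMVMIIMFVIFIVVIFFNENFTGQGE
GENRRLIFLFVLVVAIFIVALLVVIISSNPASARVRDGSNQTDDDVGGKPRAYRNLVIVA
LIIILAIVVLLMLIVFHEDSNADYQWAEGDKATRE
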