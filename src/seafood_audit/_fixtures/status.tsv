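species	category
Anguilla anguilla	CR
Anguilla rostrata	EN
Clupea pallasii	LC
Coryphaena hippurus	LC
Crassostrea virginica	LC
Dosidicus gigas	DD
Evynnis cardinalis	EN
Gadus chalcogrammus	LC
Gadus macrocephalus	LC
Gadus morhua	VU
Hippoglossus hippoglossus	VU
Hippoglossus stenolepis	VU
Katsuwonus pelamis	LC
Loligo vulgaris	DD
Lutjanus malabaricus	VU
Lutjanus russellii	VU
Magallana gigas	LC
Makaira nigricans	VU
Melanogrammus aeglefinus	VU
Mercenaria mercenaria	LC
Merluccius angustimanus	DD
Merluccius gayi	DD
Merluccius productus	DD
Micromesistius australis	LC
Micropogonias undulatus	LC
Morone chrysops	LC
Mytilus edulis	LC
Oncorhynchus gorbuscha	LC
Oncorhynchus keta	LC
Oncorhynchus kisutch	LC
Oncorhynchus nerka	LC
Oncorhynchus tshawytscha	LC
Osmerus mordax	LC
Pangasianodon hypophthalmus	EN
Panulirus argus	DD
Placopecten magellanicus	LC
Pleuronectes platessa	LC
Pollachius virens	LC
Pseudocardium sachalinense	LC
Rastrelliger brachysoma	DD
Salmo salar	LC
Salvelinus alpinus	LC
Sander vitreus	LC
Scomber japonicus	NT
Scomber scombrus	LC
Sebastes alutus	VU
Sebastes borealis	VU
Sebastes brevispinis	VU
Sebastes fasciatus	VU
Sebastes flavidus	VU
Sebastes mystinus	VU
Sebastes pinniger	VU
Sebastes serranoides	VU
Sebastes zacentrus	VU
Sepia aculeata	LC
Sepia officinalis	DD
Seriola dumerili	LC
Seriola quinqueradiata	LC
Solea solea	VU
Thunnus alalunga	NT
Thunnus albacares	NT
Thunnus obesus	VU
Thunnus thynnus	EN
Trachurus japonicus	NT
Venerupis philippinarum	LC
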