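#!/usr/bin/env python
"""Regenerate the packaged survey fixture TSVs.

The fixture transcribes the published per-market-name mislabeling tables of
the Calgary seafood survey (109 invertebrate and 347 finfish products,
2014-2020) into per-sample records, together with the authority-list
snapshot and IUCN status snapshot that reproduce the survey's published
classification of every record.  Fields the survey did not print per sample
(the barcode species of correctly labeled products, the year of individual
records) are completed deterministically and marked ``imputed``.

Run from the repository root:

    python scripts/build_fixtures.py

Outputs land in ``src/seafood_audit/_fixtures/`` with a sha256 manifest.
"""

from __future__ import annotations

import csv
import hashlib
import json
import sys
from collections import Counter
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "src" / "seafood_audit" / "_fixtures"

sys.path.insert(0, str(ROOT / "src"))

from seafood_audit.authority import normalize_name  # noqa: E402

# --------------------------------------------------------------------------
# Authority-list snapshot.
# (name, list_status, species-or-expectation, alias_of, multi_referent,
#  taxon_group)
# Genus-wide allowances are written "genus:<Name>".  For invalid names the
# species column records what a buyer could conceivably have expected.
# --------------------------------------------------------------------------

AUTHORITY_INVERTEBRATE = [
    # bivalves
    ("atlantic oyster", "on_list", "Crassostrea virginica", "", 0, "Bivalvia"),
    ("pacific oyster", "on_list", "Magallana gigas", "", 0, "Bivalvia"),
    ("oyster", "on_list",
     "Crassostrea virginica;Magallana gigas;Ostrea edulis", "", 0, "Bivalvia"),
    ("malpeque oyster", "alias", "", "atlantic oyster", 0, "Bivalvia"),
    ("malpeques", "alias", "", "atlantic oyster", 0, "Bivalvia"),
    ("torpedo bay oyster", "alias", "", "oyster", 0, "Bivalvia"),
    ("mussel", "on_list",
     "Mytilus edulis;Mytilus galloprovincialis;Perna canaliculus",
     "", 0, "Bivalvia"),
    ("atlantic bay mussel", "on_list", "Mytilus edulis", "", 0, "Bivalvia"),
    ("atlantic mussel", "alias", "", "atlantic bay mussel", 0, "Bivalvia"),
    ("scallop", "on_list",
     "Placopecten magellanicus;Patinopecten yessoensis;Argopecten irradians",
     "", 0, "Bivalvia"),
    ("atlantic scallop", "on_list", "Placopecten magellanicus", "", 0, "Bivalvia"),
    ("clam", "on_list",
     "Mercenaria mercenaria;Mya arenaria;Spisula solidissima;"
     "Venerupis philippinarum", "", 0, "Bivalvia"),
    ("cherrystone", "on_list", "Mercenaria mercenaria", "", 0, "Bivalvia"),
    ("cherrystone clam", "alias", "", "cherrystone", 0, "Bivalvia"),
    ("manila clam", "on_list", "Venerupis philippinarum", "", 0, "Bivalvia"),
    ("surf clam", "on_list", "Spisula solidissima", "", 0, "Bivalvia"),
    # cephalopods
    ("squid", "on_list",
     "Doryteuthis opalescens;Loligo vulgaris;Todarodes pacificus;"
     "Dosidicus gigas", "", 0, "Cephalopoda"),
    ("calamari", "on_list",
     "Loligo vulgaris;Doryteuthis opalescens;Todarodes pacificus",
     "", 0, "Cephalopoda"),
    ("california market squid", "on_list", "Doryteuthis opalescens",
     "", 0, "Cephalopoda"),
    ("california squid", "alias", "", "california market squid",
     0, "Cephalopoda"),
    ("japanese flying squid", "on_list", "Todarodes pacificus",
     "", 0, "Cephalopoda"),
    ("giant squid", "alias", "", "squid", 0, "Cephalopoda"),
    ("cuttlefish", "on_list", "Sepia officinalis;Sepia pharaonis",
     "", 0, "Cephalopoda"),
    ("squid cuttlefish", "on_list",
     "Sepia officinalis;Loligo vulgaris;Doryteuthis opalescens;"
     "Todarodes pacificus", "", 0, "Cephalopoda"),
    ("octopus", "on_list", "Octopus vulgaris;Enteroctopus dofleini",
     "", 0, "Cephalopoda"),
    ("tako", "alias", "", "octopus", 0, "Cephalopoda"),
    # malacostracans
    ("shrimp", "on_list",
     "genus:Penaeus;genus:Pandalus;Pleoticus muelleri", "", 0, "Malacostraca"),
    ("prawn", "on_list", "genus:Penaeus;Pandalus borealis",
     "", 0, "Malacostraca"),
    ("pacific white shrimp", "on_list",
     "Penaeus vannamei;Penaeus stylirostris", "", 0, "Malacostraca"),
    ("black tiger shrimp", "on_list", "Penaeus monodon", "", 0, "Malacostraca"),
    ("argentine prawn", "alias", "", "shrimp", 0, "Malacostraca"),
    ("freshwater shrimp", "on_list", "genus:Macrobrachium",
     "", 0, "Malacostraca"),
    ("colossal freshwater shrimp", "alias", "", "freshwater shrimp",
     0, "Malacostraca"),
    ("crab", "on_list",
     "Callinectes sapidus;Cancer pagurus;Metacarcinus magister;"
     "Chionoecetes opilio;Paralithodes camtschaticus", "", 0, "Malacostraca"),
    ("red crab", "on_list", "Chaceon quinquedens", "", 0, "Malacostraca"),
    ("king crab", "on_list", "genus:Paralithodes", "", 0, "Malacostraca"),
    ("snow crab", "on_list", "genus:Chionoecetes", "", 0, "Malacostraca"),
    ("southern king crab", "on_list", "Lithodes santolla", "", 0, "Malacostraca"),
    ("lobster", "on_list", "Homarus americanus;Homarus gammarus",
     "", 0, "Malacostraca"),
    ("spiny lobster", "on_list", "genus:Panulirus", "", 0, "Malacostraca"),
    # echinoderms & mixed
    ("sea urchin", "on_list",
     "Strongylocentrotus purpuratus;Mesocentrotus franciscanus",
     "", 0, "Echinoidea"),
    ("uni", "alias", "", "sea urchin", 0, "Echinoidea"),
    ("seafood medley mix", "unregulated", "", "", 0, "mixed"),
    ("seafood medley", "unregulated", "", "", 0, "mixed"),
]

AUTHORITY_FINFISH = [
    # salmonids
    ("atlantic salmon", "on_list", "Salmo salar", "", 0, "Salmonidae"),
    ("salmon", "on_list", "Salmo salar", "", 0, "Salmonidae"),
    ("sockeye salmon", "on_list", "Oncorhynchus nerka", "", 0, "Salmonidae"),
    ("pink salmon", "on_list", "Oncorhynchus gorbuscha", "", 0, "Salmonidae"),
    ("chinook salmon", "on_list", "Oncorhynchus tshawytscha", "", 0, "Salmonidae"),
    ("coho salmon", "on_list", "Oncorhynchus kisutch", "", 0, "Salmonidae"),
    ("chum salmon", "on_list", "Oncorhynchus keta", "", 0, "Salmonidae"),
    ("steelhead trout", "on_list", "Oncorhynchus mykiss", "", 0, "Salmonidae"),
    ("steelhead salmon", "on_list", "Oncorhynchus mykiss", "", 0, "Salmonidae"),
    ("trout", "on_list", "Oncorhynchus mykiss", "", 0, "Salmonidae"),
    ("arctic char", "on_list", "genus:Salvelinus", "", 0, "Salmonidae"),
    ("char", "on_list", "Salvelinus alpinus", "", 0, "Salmonidae"),
    ("lake whitefish", "on_list", "Coregonus clupeaformis", "", 0, "Salmonidae"),
    ("canadian lake whitefish", "alias", "", "lake whitefish", 0, "Salmonidae"),
    ("whitefish", "on_list", "genus:Coregonus", "", 0, "Salmonidae"),
    ("alaskan salmon", "invalid", "Oncorhynchus nerka", "", 1, "Salmonidae"),
    ("pacific salmon", "invalid", "Oncorhynchus gorbuscha", "", 1, "Salmonidae"),
    # scombrids
    ("tuna", "on_list", "genus:Thunnus;Katsuwonus pelamis", "", 0, "Scombridae"),
    ("yellowfin tuna", "on_list", "Thunnus albacares", "", 0, "Scombridae"),
    ("bigeye tuna", "on_list", "Thunnus obesus", "", 0, "Scombridae"),
    ("albacore tuna", "on_list", "Thunnus alalunga", "", 0, "Scombridae"),
    ("skipjack tuna", "on_list", "Katsuwonus pelamis", "", 0, "Scombridae"),
    ("bluefin tuna", "on_list", "Thunnus thynnus;Thunnus orientalis",
     "", 0, "Scombridae"),
    ("ahi tuna", "alias", "", "yellowfin tuna", 1, "Scombridae"),
    ("red tuna", "alias", "", "tuna", 1, "Scombridae"),
    ("white tuna", "alias", "", "tuna", 1, "Scombridae"),
    ("bf negi toro", "alias", "", "tuna", 0, "Scombridae"),
    ("mackerel", "on_list", "Scomber scombrus;Scomber japonicus",
     "", 0, "Scombridae"),
    ("atlantic mackerel", "on_list", "Scomber scombrus", "", 0, "Scombridae"),
    ("japanese mackerel", "invalid", "Scomber scombrus", "", 1, "Scombridae"),
    ("short mackerel", "on_list",
     "Rastrelliger brachysoma;Rastrelliger kanagurta", "", 0, "Scombridae"),
    # carangids
    ("jack mackerel", "on_list", "genus:Trachurus", "", 0, "Carangidae"),
    ("amberjack", "on_list", "genus:Seriola", "", 0, "Carangidae"),
    ("japanese amberjack", "on_list", "Seriola quinqueradiata",
     "", 0, "Carangidae"),
    ("hamachi", "alias", "", "japanese amberjack", 0, "Carangidae"),
    ("yellowtail", "alias", "", "japanese amberjack", 1, "Carangidae"),
    ("hamachi yellow tail tuna", "invalid", "Seriola quinqueradiata",
     "", 0, "Carangidae"),
    ("hamachi yellowtail jackfish", "invalid", "Seriola quinqueradiata",
     "", 0, "Carangidae"),
    # gadids
    ("cod", "on_list", "Gadus morhua;Gadus macrocephalus", "", 0, "Gadidae"),
    ("atlantic cod", "on_list", "Gadus morhua", "", 0, "Gadidae"),
    ("pacific cod", "on_list", "Gadus macrocephalus", "", 0, "Gadidae"),
    ("alaskan cod", "invalid",
     "Boreogadus saida;Gadus ogac;Gadus macrocephalus", "", 1, "Gadidae"),
    ("arctic cod", "on_list", "Boreogadus saida", "", 0, "Gadidae"),
    ("alaska pollock", "on_list", "Gadus chalcogrammus", "", 0, "Gadidae"),
    ("pollock", "on_list", "Pollachius virens;Gadus chalcogrammus",
     "", 0, "Gadidae"),
    ("alaska pollock pacific whiting imitation crab", "on_list",
     "Gadus chalcogrammus;Merluccius productus", "", 0, "Gadidae"),
    ("haddock", "on_list", "Melanogrammus aeglefinus", "", 0, "Gadidae"),
    ("north atlantic haddock", "alias", "", "haddock", 0, "Gadidae"),
    ("blue cod", "on_list",
     "Micromesistius australis;Micromesistius poutassou", "", 0, "Gadidae"),
    ("new zealand blue cod", "alias", "", "blue cod", 0, "Gadidae"),
    ("imitation crab", "unregulated", "", "", 0, "Gadidae"),
    # snappers & rockfishes (shared labels; families merged)
    ("snapper", "on_list", "genus:Lutjanus", "", 0, "Lutjanidae/Scorpaenidae"),
    ("red snapper", "on_list", "Lutjanus campechanus",
     "", 0, "Lutjanidae/Scorpaenidae"),
    ("yellowtail snapper", "on_list", "Ocyurus chrysurus",
     "", 0, "Lutjanidae/Scorpaenidae"),
    ("pacific yellowtail snapper", "alias", "", "yellowtail snapper",
     1, "Lutjanidae/Scorpaenidae"),
    ("pacific snapper", "on_list",
     "Sebastes flavidus;Sebastes brevispinis;Sebastes borealis;"
     "Sebastes pinniger", "", 0, "Lutjanidae/Scorpaenidae"),
    ("rockfish", "on_list", "genus:Sebastes", "", 0, "Lutjanidae/Scorpaenidae"),
    ("pacific rockfish", "alias", "", "rockfish", 1, "Lutjanidae/Scorpaenidae"),
    ("yellowtail rockfish", "on_list", "Sebastes flavidus",
     "", 0, "Lutjanidae/Scorpaenidae"),
    ("ocean perch", "on_list", "Sebastes alutus;Sebastes fasciatus",
     "", 0, "Lutjanidae/Scorpaenidae"),
    # flatfishes
    ("halibut", "on_list",
     "Hippoglossus hippoglossus;Hippoglossus stenolepis",
     "", 0, "Pleuronectidae"),
    ("pacific halibut", "on_list", "Hippoglossus stenolepis",
     "", 0, "Pleuronectidae"),
    ("sole", "on_list",
     "Solea solea;Pleuronectes platessa;Limanda aspera",
     "", 0, "Pleuronectidae"),
    ("pacific sole", "alias", "", "sole", 0, "Pleuronectidae"),
    # eels
    ("eel", "on_list", "Anguilla rostrata", "", 0, "Anguillidae"),
    ("american eel", "on_list", "Anguilla rostrata", "", 0, "Anguillidae"),
    ("freshwater eel", "alias", "", "eel", 0, "Anguillidae"),
    ("unagi", "alias", "", "eel", 0, "Anguillidae"),
    ("dancing eel", "alias", "", "eel", 0, "Anguillidae"),
    ("saltwater eel", "invalid", "Anguilla rostrata", "", 0, "Anguillidae"),
    ("sea eel", "invalid", "Ophichthus remiger", "", 1, "Anguillidae"),
    ("conger eel", "on_list", "genus:Conger", "", 0, "Congridae"),
    # everything else
    ("basa", "on_list", "Pangasius bocourti;Pangasius djambal",
     "", 0, "Pangasiidae"),
    ("bocourti", "on_list",
     "Pangasius bocourti;Pangasius djambal;Pangasianodon hypophthalmus",
     "", 0, "Pangasiidae"),
    ("tilapia", "on_list", "genus:Oreochromis", "", 0, "Cichlidae"),
    ("pickerel", "on_list", "Sander vitreus;Sander canadensis",
     "", 0, "Percidae"),
    ("walleye", "on_list", "Sander vitreus", "", 0, "Percidae"),
    ("butterfish oilfish", "on_list",
     "Peprilus triacanthus;Ruvettus pretiosus", "", 0, "Stromateidae"),
    ("escolar", "on_list", "Lepidocybium flavobrunneum", "", 0, "Gempylidae"),
    ("corvina", "on_list", "Cilus gilberti;Argyrosomus regius",
     "", 0, "Sciaenidae"),
    ("croaker", "on_list", "Micropogonias undulatus", "", 0, "Sciaenidae"),
    ("yellow croaker", "on_list", "Larimichthys polyactis", "", 0, "Sciaenidae"),
    ("smelt", "on_list", "Osmerus mordax", "", 0, "Osmeridae"),
    ("freshwater smelt", "alias", "", "smelt", 1, "Osmeridae"),
    ("golden threadfin bream", "on_list", "Nemipterus virgatus",
     "", 0, "Nemipteridae"),
    ("marlin", "on_list", "Kajikia audax;Istiompax indica",
     "", 0, "Istiophoridae"),
    ("blue marlin", "on_list", "Makaira nigricans", "", 0, "Istiophoridae"),
    ("sea bass", "on_list", "Dicentrarchus labrax;Lateolabrax japonicus",
     "", 0, "Moronidae"),
    ("white bass", "on_list", "Morone chrysops", "", 0, "Moronidae"),
    ("mahi mahi", "on_list", "Coryphaena hippurus;Coryphaena equiselis",
     "", 0, "Coryphaenidae"),
    ("pacific herring", "on_list", "Clupea pallasii", "", 0, "Clupeidae"),
    ("ponyfish", "on_list", "genus:Leiognathus", "", 0, "Leiognathidae"),
]

# --------------------------------------------------------------------------
# Per-market-name records transcribed from the survey's mislabeling tables.
# name -> list of (count, category, candidate species, imputed)
# category: P properly labeled, S semantic, IN invalid name,
#           PS product substitution, U unregulated.
# Candidate species of correctly labeled products are not printed in the
# survey tables and are imputed with an acceptable species (imputed=1).
# --------------------------------------------------------------------------

P, S, IN, PS, U = "properly_labeled", "semantic", "invalid_name", \
    "product_substitution", "unregulated"

RECORDS_INVERTEBRATE = {
    "Argentine Prawn": [(1, S, "Pleoticus muelleri", 0)],
    "Atlantic Mussel": [(2, S, "Mytilus edulis", 0)],
    "Atlantic Scallop": [(1, P, "Placopecten magellanicus", 1)],
    "Black Tiger Shrimp": [(2, P, "Penaeus monodon", 1)],
    "Calamari": [(1, P, "Loligo vulgaris", 1)],
    "California Squid": [(1, S, "Doryteuthis opalescens", 0)],
    "Cherrystone Clam": [(1, S, "Mercenaria mercenaria", 0)],
    "Clam": [(2, P, "Mya arenaria", 1)],
    "Colossal Freshwater Shrimp": [(1, S, "Macrobrachium rosenbergii", 0)],
    "Crab": [
        (3, P, "Metacarcinus magister", 1),
        (1, PS, "Nemipterus hexodon", 0),
        (1, PS, "Priacanthus hamrur;Priacanthus prolixus", 0),
        (1, PS, "Chaceon quinquedens;Chaceon chuni", 0),
    ],
    "Cuttlefish": [
        (1, P, "Sepia officinalis", 1),
        (1, PS, "Sepiella inermis", 0),
        (1, PS, "Dentex tumifrons;Parargyrops edita;Evynnis cardinalis", 0),
        (1, PS,
         "Pangasius bocourti;Pangasius djambal;Pangasianodon hypophthalmus",
         0),
    ],
    "Giant Squid": [(1, S, "Todarodes pacificus", 0)],
    "King Crab": [
        (1, PS,
         "Merluccius angustimanus;Merluccius productus;Merluccius gayi", 0),
    ],
    "Lobster": [
        (2, P, "Homarus americanus", 1),
        (1, PS, "Panulirus argus", 0),
    ],
    "Malpeque Oyster": [
        (3, S, "Crassostrea virginica", 0),
        (1, PS, "Magallana gigas", 0),
    ],
    "Malpeques": [(1, S, "Crassostrea virginica", 0)],
    "Manila Clam": [(1, P, "Venerupis philippinarum", 1)],
    "Mussel": [(6, P, "Mytilus edulis", 1)],
    "Octopus": [
        (7, P, "Octopus vulgaris", 1),
        (1, PS, "Amphioctopus sp.", 0),
        (1, PS, "Amphioctopus aegina", 0),
        (1, PS, "Dosidicus gigas", 0),
        (2, PS, "Todarodes pacificus", 0),
    ],
    "Oyster": [(1, P, "Crassostrea virginica", 1)],
    "Pacific White Shrimp": [(10, P, "Penaeus vannamei", 1)],
    "Prawn": [
        (2, P, "Penaeus vannamei", 1),
        (1, P, "Pandalus borealis", 1),
    ],
    "Scallop": [(2, P, "Placopecten magellanicus", 1)],
    "Seafood Medley/Mix": [(2, U, "Penaeus vannamei", 1)],
    "Shrimp": [
        (19, P, "Penaeus vannamei", 1),
        (1, PS, "Solenocera crassicornis", 0),
    ],
    "Snow Crab": [(1, PS, "Chaceon quinquedens;Chaceon chuni", 0)],
    "Southern King Crab": [(1, P, "Lithodes santolla", 1)],
    "Squid": [
        (4, P, "Doryteuthis opalescens", 1),
        (3, P, "Loligo vulgaris", 1),
        (1, PS, "Sepia aculeata", 0),
        (1, PS, "Sepia recurvirostra", 0),
    ],
    "Squid/Cuttlefish": [(1, P, "Sepia officinalis", 1)],
    "Surf Clam": [(4, PS, "Pseudocardium sachalinense", 0)],
    "Tako": [(2, S, "Octopus vulgaris", 0)],
    "Torpedo Bay Oyster": [(1, S, "Magallana gigas", 0)],
    "Uni": [
        (1, S, "Strongylocentrotus purpuratus;Mesocentrotus franciscanus", 0),
    ],
}

RECORDS_FINFISH = {
    "Ahi Tuna": [
        (3, S, "Thunnus albacares", 0),
        (1, PS, "Thunnus thynnus;Thunnus orientalis", 0),
        (2, PS, "Thunnus obesus", 0),
    ],
    "Alaska Pollock": [(5, P, "Gadus chalcogrammus", 1)],
    "Alaska Pollock/Pacific Whiting (Imitation Crab)": [
        (1, P, "Gadus chalcogrammus", 1),
    ],
    "Alaskan Cod": [
        (1, IN, "Boreogadus saida;Gadus ogac;Gadus macrocephalus", 0),
    ],
    "Alaskan Salmon": [
        (1, IN, "Oncorhynchus nerka", 0),
        (1, PS, "Sebastes alutus", 0),
    ],
    "Albacore Tuna": [
        (1, P, "Thunnus alalunga", 1),
        (1, PS, "Oreochromis niloticus", 0),
    ],
    "Amberjack": [(1, P, "Seriola dumerili", 1)],
    "Arctic Char": [(1, P, "Salvelinus alpinus", 1)],
    "Atlantic Cod": [(1, PS, "Gadus macrocephalus", 0)],
    "Atlantic Salmon": [(30, P, "Salmo salar", 1)],
    "Basa": [(15, P, "Pangasius bocourti", 1)],
    "BF Negi Toro": [(1, S, "Thunnus thynnus", 0)],
    "Bigeye Tuna": [(1, P, "Thunnus obesus", 1)],
    "Bluefin Tuna": [(2, P, "Thunnus thynnus", 1)],
    "Butterfish/Oilfish": [(1, PS, "Lepidocybium flavobrunneum", 0)],
    "Canadian Lake Whitefish": [(1, S, "Coregonus clupeaformis", 0)],
    "Chinook Salmon": [(1, P, "Oncorhynchus tshawytscha", 1)],
    "Cod": [
        (15, P, "Gadus morhua", 1),
        (2, P, "Gadus macrocephalus", 1),
        (1, PS, "Salvelinus alpinus", 0),
        (1, PS, "Micromesistius australis", 0),
    ],
    "Coho Salmon": [(1, P, "Oncorhynchus kisutch", 1)],
    "Conger Eel": [(1, P, "Conger myriaster", 1)],
    "Corvina": [(1, PS, "Micropogonias undulatus", 0)],
    "Dancing Eel": [(1, S, "Anguilla rostrata", 0)],
    "Eel": [
        (1, P, "Anguilla rostrata", 1),
        (1, PS, "Anguilla anguilla", 0),
    ],
    "Freshwater Eel": [
        (4, S, "Anguilla rostrata", 0),
        (1, PS, "Anguilla anguilla", 0),
    ],
    "Freshwater Smelt": [(1, S, "Osmerus mordax", 0)],
    "Golden Threadfin Bream": [(1, PS, "Nemipterus japonicus", 0)],
    "Haddock": [(3, P, "Melanogrammus aeglefinus", 1)],
    "Halibut": [(13, P, "Hippoglossus hippoglossus", 1)],
    "Hamachi": [(1, S, "Seriola quinqueradiata", 0)],
    "Hamachi– Yellow Tail Tuna": [(1, IN, "Seriola quinqueradiata", 0)],
    "Hamachi– Yellowtail Jackfish": [(1, IN, "Seriola quinqueradiata", 0)],
    "Imitation Crab": [(2, U, "Gadus chalcogrammus", 1)],
    "Jack Mackerel": [(1, P, "Trachurus japonicus", 1)],
    "Japanese Mackerel": [(1, IN, "Scomber scombrus", 0)],
    "Mackerel": [(10, P, "Scomber japonicus", 1)],
    "Mahi-mahi": [(1, P, "Coryphaena hippurus", 1)],
    "Marlin": [(1, PS, "Makaira nigricans", 0)],
    "New Zealand Blue Cod": [(2, S, "Micromesistius australis", 0)],
    "North Atlantic Haddock": [(1, S, "Melanogrammus aeglefinus", 0)],
    "Ocean Perch": [(1, P, "Sebastes alutus", 1)],
    "Pacific Cod": [
        (8, P, "Gadus macrocephalus", 1),
        (3, PS, "Gadus morhua", 0),
    ],
    "Pacific Halibut": [(1, P, "Hippoglossus stenolepis", 1)],
    "Pacific Herring": [(1, P, "Clupea pallasii", 1)],
    "Pacific Rockfish": [
        (1, S, "Sebastes flavidus;Sebastes serranoides", 0),
        (1, S, "Sebastes pinniger", 0),
    ],
    "Pacific Salmon": [(1, IN, "Oncorhynchus gorbuscha", 0)],
    "Pacific Snapper": [
        (6, P, "Sebastes flavidus", 1),
        (1, PS, "Sebastes zacentrus", 0),
    ],
    "Pacific Sole": [(1, S, "Limanda aspera;Limanda limanda", 0)],
    "Pacific Yellowtail Snapper": [
        (1, PS, "Sebastes brevispinis;Sebastes zacentrus;Sebastes borealis", 0),
        (1, PS, "Sebastes flavidus;Sebastes serranoides", 0),
    ],
    "Pickerel": [(4, P, "Sander vitreus", 1)],
    "Pink Salmon": [(2, P, "Oncorhynchus gorbuscha", 1)],
    "Pollock": [
        (1, P, "Pollachius virens", 1),
        (1, PS, "Limanda aspera", 0),
    ],
    "Ponyfish": [(1, P, "Leiognathus equulus", 1)],
    "Red Snapper": [
        (1, PS, "Lutjanus malabaricus", 0),
        (1, PS, "Lutjanus russellii;Lutjanus johnii", 0),
        (1, PS, "Sebastes flavidus;Sebastes serranoides", 0),
        (13, PS, "Oreochromis niloticus", 0),
    ],
    "Red Tuna": [(8, S, "Thunnus thynnus", 0)],
    "Salmon": [
        (24, P, "Salmo salar", 1),
        (1, PS, "Thunnus alalunga;Thunnus obesus", 0),
        (2, PS, "Oncorhynchus tshawytscha", 0),
        (2, PS, "Oncorhynchus gorbuscha", 0),
        (9, PS, "Oncorhynchus mykiss", 0),
        (1, PS, "Oncorhynchus nerka", 0),
    ],
    "Saltwater Eel": [(1, IN, "Anguilla rostrata", 0)],
    "Sea Bass": [(1, PS, "Oncorhynchus keta", 0)],
    "Sea Eel": [(1, IN, "Ophichthus remiger", 0)],
    "Short Mackerel": [(1, P, "Rastrelliger brachysoma", 1)],
    "Skipjack Tuna": [(1, P, "Katsuwonus pelamis", 1)],
    "Snapper": [
        (2, PS, "Sebastes flavidus;Sebastes serranoides;Sebastes mystinus", 0),
        (6, PS, "Oreochromis niloticus", 0),
    ],
    "Sockeye Salmon": [(20, P, "Oncorhynchus nerka", 1)],
    "Sole": [
        (4, P, "Solea solea", 1),
        (2, P, "Pleuronectes platessa", 1),
    ],
    "Steelhead Salmon": [(3, P, "Oncorhynchus mykiss", 1)],
    "Steelhead Trout": [(4, P, "Oncorhynchus mykiss", 1)],
    "Tilapia": [(7, P, "Oreochromis niloticus", 1)],
    "Trout": [(1, P, "Oncorhynchus mykiss", 1)],
    "Tuna": [
        (10, P, "Thunnus thynnus", 1),
        (12, P, "Thunnus obesus", 1),
        (5, P, "Thunnus albacares", 1),
        (1, PS, "Lepidocybium flavobrunneum", 0),
    ],
    "Unagi": [(1, S, "Anguilla rostrata", 0)],
    "Walleye": [(3, P, "Sander vitreus", 1)],
    "White Bass": [(1, P, "Morone chrysops", 1)],
    "White Tuna": [(2, S, "Thunnus alalunga", 0)],
    "Whitefish": [(1, PS, "Salvelinus alpinus", 0)],
    "Yellow Croaker": [(1, P, "Larimichthys polyactis", 1)],
    "Yellowfin Tuna": [(3, P, "Thunnus albacares", 1)],
    "Yellowtail": [
        (9, S, "Seriola quinqueradiata", 0),
        (1, PS, "Oreochromis niloticus", 0),
    ],
    "Yellowtail Rockfish": [(1, PS, "Sebastes alutus", 0)],
    "Yellowtail Snapper": [(1, PS, "Sebastes flavidus;Sebastes serranoides", 0)],
}

# --------------------------------------------------------------------------
# Year-by-year tallies: year -> (n, S, IN, PS, %all, %cons).
# --------------------------------------------------------------------------

YEARS_INVERTEBRATE = {
    2016: (1, 0, 0, 1, 100.0, 100.0),
    2017: (1, 0, 0, 1, 100.0, 100.0),
    2018: (47, 4, 0, 14, 38.3, 29.8),
    2019: (16, 3, 0, 3, 37.5, 18.8),
    2020: (44, 8, 0, 3, 25.0, 6.8),
}
YEARS_FINFISH = {
    2014: (19, 0, 0, 6, 31.6, 31.6),
    2016: (57, 5, 0, 12, 29.8, 21.1),
    2017: (132, 19, 6, 28, 40.2, 25.8),
    2018: (62, 10, 0, 10, 32.2, 16.1),
    2019: (60, 4, 2, 7, 21.7, 15.0),
    2020: (17, 0, 0, 3, 17.6, 17.6),
}

# --------------------------------------------------------------------------
# IUCN status snapshot (species absent from the table are Not Applicable).
# --------------------------------------------------------------------------

STATUS = {
    # invertebrates
    "Mytilus edulis": "LC",
    "Crassostrea virginica": "LC",
    "Magallana gigas": "LC",
    "Placopecten magellanicus": "LC",
    "Mercenaria mercenaria": "LC",
    "Venerupis philippinarum": "LC",
    "Pseudocardium sachalinense": "LC",
    "Sepia aculeata": "LC",
    "Sepia officinalis": "DD",
    "Loligo vulgaris": "DD",
    "Dosidicus gigas": "DD",
    "Panulirus argus": "DD",
    # finfish - least concern
    "Salmo salar": "LC",
    "Oncorhynchus nerka": "LC",
    "Oncorhynchus gorbuscha": "LC",
    "Oncorhynchus tshawytscha": "LC",
    "Oncorhynchus kisutch": "LC",
    "Oncorhynchus keta": "LC",
    "Salvelinus alpinus": "LC",
    "Gadus macrocephalus": "LC",
    "Gadus chalcogrammus": "LC",
    "Pollachius virens": "LC",
    "Micromesistius australis": "LC",
    "Scomber scombrus": "LC",
    "Katsuwonus pelamis": "LC",
    "Seriola quinqueradiata": "LC",
    "Seriola dumerili": "LC",
    "Clupea pallasii": "LC",
    "Sander vitreus": "LC",
    "Morone chrysops": "LC",
    "Coryphaena hippurus": "LC",
    "Micropogonias undulatus": "LC",
    "Osmerus mordax": "LC",
    "Pleuronectes platessa": "LC",
    # near threatened
    "Thunnus albacares": "NT",
    "Thunnus alalunga": "NT",
    "Scomber japonicus": "NT",
    "Trachurus japonicus": "NT",
    # vulnerable
    "Gadus morhua": "VU",
    "Melanogrammus aeglefinus": "VU",
    "Thunnus obesus": "VU",
    "Hippoglossus hippoglossus": "VU",
    "Hippoglossus stenolepis": "VU",
    "Solea solea": "VU",
    "Makaira nigricans": "VU",
    "Lutjanus malabaricus": "VU",
    "Lutjanus russellii": "VU",
    "Sebastes flavidus": "VU",
    "Sebastes serranoides": "VU",
    "Sebastes mystinus": "VU",
    "Sebastes pinniger": "VU",
    "Sebastes zacentrus": "VU",
    "Sebastes brevispinis": "VU",
    "Sebastes borealis": "VU",
    "Sebastes alutus": "VU",
    "Sebastes fasciatus": "VU",
    # endangered / critically endangered
    "Thunnus thynnus": "EN",
    "Anguilla rostrata": "EN",
    "Evynnis cardinalis": "EN",
    "Pangasianodon hypophthalmus": "EN",
    "Anguilla anguilla": "CR",
    # data deficient
    "Rastrelliger brachysoma": "DD",
    "Merluccius productus": "DD",
    "Merluccius angustimanus": "DD",
    "Merluccius gayi": "DD",
}


def expand_records(cohort: str, spec: dict, years: dict, prefix: str):
    """Per-sample rows, with years filled greedily to match the year table."""
    group_of = {
        normalize_name(n): g
        for n, _, _, _, _, g in AUTHORITY_INVERTEBRATE + AUTHORITY_FINFISH
    }
    records = []
    for raw_name in sorted(spec):
        for count, cat, cands, imputed in spec[raw_name]:
            for _ in range(count):
                records.append(
                    {
                        "cohort": cohort,
                        "market_name_raw": raw_name,
                        "taxon_group": group_of[normalize_name(raw_name)],
                        "barcode_candidates": cands,
                        "expected_category": cat,
                        "imputed": imputed,
                        "source": f"per-name survey table, row {raw_name!r}",
                    }
                )
    # Remaining "slot" quota per (year, category); unregulated and properly
    # labeled records share the not-mislabeled slots.
    quota = {}
    for year, (n, s, inv, ps, _, _) in years.items():
        quota[(year, S)] = s
        quota[(year, IN)] = inv
        quota[(year, PS)] = ps
        quota[(year, "ok")] = n - s - inv - ps
    year_order = sorted(years)
    for rec in records:
        key_cat = rec["expected_category"]
        if key_cat in (P, U):
            key_cat = "ok"
        year = next(y for y in year_order if quota[(y, key_cat)] > 0)
        quota[(year, key_cat)] -= 1
        rec["year"] = year
    assert all(v == 0 for v in quota.values()), quota
    records.sort(key=lambda r: (r["year"], r["market_name_raw"]))
    for i, rec in enumerate(records, start=1):
        rec["sample_id"] = f"{prefix}-{i:04d}"
    return records


def sanity_check(inv, fin):
    """Internal consistency against the survey's printed totals."""
    assert len(inv) == 109 and len(fin) == 347
    ci = Counter(r["expected_category"] for r in inv)
    cf = Counter(r["expected_category"] for r in fin)
    assert (ci[S], ci[IN], ci[PS], ci[U]) == (15, 0, 22, 2), ci
    assert (cf[S], cf[IN], cf[PS], cf[U]) == (38, 8, 66, 2), cf


def write_tsv(path: Path, fieldnames, rows):
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=fieldnames, delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        writer.writerows(rows)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    inv = expand_records("invertebrate", RECORDS_INVERTEBRATE,
                         YEARS_INVERTEBRATE, "INV")
    fin = expand_records("finfish", RECORDS_FINFISH, YEARS_FINFISH, "FIN")
    sanity_check(inv, fin)

    record_cols = [
        "sample_id", "cohort", "year", "market_name_raw", "taxon_group",
        "barcode_candidates", "expected_category", "imputed", "source",
    ]
    write_tsv(OUT / "records_invertebrates.tsv", record_cols, inv)
    write_tsv(OUT / "records_finfish.tsv", record_cols, fin)

    auth_rows = [
        {
            "market_name": name,
            "list_status": status,
            "species": species,
            "alias_of": alias,
            "multi_referent": multi,
            "taxon_group": group,
            "cohort": cohort,
        }
        for cohort, table in (
            ("invertebrate", AUTHORITY_INVERTEBRATE),
            ("finfish", AUTHORITY_FINFISH),
        )
        for name, status, species, alias, multi, group in table
    ]
    write_tsv(
        OUT / "authority.tsv",
        ["market_name", "list_status", "species", "alias_of",
         "multi_referent", "taxon_group", "cohort"],
        auth_rows,
    )
    write_tsv(
        OUT / "status.tsv",
        ["species", "category"],
        [{"species": sp, "category": cat} for sp, cat in sorted(STATUS.items())],
    )

    # Per-name count transcription (the audit surface tests aggregate
    # against this) and the year table.
    name_rows = []
    for cohort, spec in (("invertebrate", RECORDS_INVERTEBRATE),
                         ("finfish", RECORDS_FINFISH)):
        for raw_name in sorted(spec):
            cats = Counter()
            for count, cat, _, _ in spec[raw_name]:
                cats[cat] += count
            name_rows.append(
                {
                    "cohort": cohort,
                    "market_name_raw": raw_name,
                    "n": sum(cats.values()),
                    "semantic": cats[S],
                    "invalid_name": cats[IN],
                    "product_substitution": cats[PS],
                }
            )
    write_tsv(
        OUT / "table_counts.tsv",
        ["cohort", "market_name_raw", "n", "semantic", "invalid_name",
         "product_substitution"],
        name_rows,
    )
    year_rows = [
        {
            "cohort": cohort,
            "year": year,
            "n": n,
            "semantic": s,
            "invalid_name": i,
            "product_substitution": ps,
            "pct_total": pt,
            "pct_conservative": pc,
        }
        for cohort, years in (("invertebrate", YEARS_INVERTEBRATE),
                              ("finfish", YEARS_FINFISH))
        for year, (n, s, i, ps, pt, pc) in sorted(years.items())
    ]
    write_tsv(
        OUT / "year_counts.tsv",
        ["cohort", "year", "n", "semantic", "invalid_name",
         "product_substitution", "pct_total", "pct_conservative"],
        year_rows,
    )

    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(OUT.glob("*.tsv"))
    }
    (OUT / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    for name in manifest:
        print(f"wrote {name}")


if __name__ == "__main__":
    main()
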