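"""Bundled name lexicon for synthetic-register generation and name screening.

Small stand-in lists of Brazilian-style given names and surnames (the
national reference list used operationally is not public).  Tokens are
upper-case, unaccented, punctuation-free — i.e. already in standardized
form.  Connectives (DA, DE, DOS, ...) are the particles that commonly
appear inside full names and are treated as valid tokens by screening.
"""

from __future__ import annotations

GIVEN_NAMES: tuple[str, ...] = (
    "MARIA", "ANA", "FRANCISCA", "ANTONIA", "ADRIANA", "JULIANA", "MARCIA",
    "FERNANDA", "PATRICIA", "ALINE", "SANDRA", "CAMILA", "AMANDA", "BRUNA",
    "JESSICA", "LETICIA", "JULIA", "LUCIANA", "VANESSA", "MARIANA", "GABRIELA",
    "VERA", "VITORIA", "LARISSA", "CLAUDIA", "BEATRIZ", "LUZIA", "LUCIA",
    "RITA", "TEREZA", "SONIA", "ROSA", "ELIANE", "RENATA", "SIMONE", "ANGELA",
    "FATIMA", "JOANA", "CRISTINA", "DANIELA", "PAULA", "CARLA", "TATIANE",
    "MONICA", "ROSANGELA", "REGINA", "APARECIDA", "ELISABETE", "MARLENE",
    "IRENE", "CELIA", "NEUSA", "IVONE", "ZILDA", "DALVA", "EDNA", "SUELI",
    "MARTA", "HELENA", "ALICE", "LAURA", "CECILIA", "CLARA", "ISABEL",
    "SOFIA", "VALENTINA", "HELOISA", "LIVIA", "LORENA", "MELISSA", "YASMIN",
    "ISADORA", "LAIS", "MILENA", "REBECA", "ESTER", "SARA", "RAQUEL", "DEBORA",
    "NATALIA", "CAROLINA", "PRISCILA", "VIVIANE", "ELAINE", "KELLY", "KARINA",
    "MICHELE", "SABRINA", "TAINA", "THAIS", "INGRID", "BARBARA", "VANIA",
    "SOLANGE", "MARGARIDA", "ODETE", "NAIR", "IRACEMA", "DIRCE", "JANDIRA",
    "JOSEFA", "SEVERINA", "RAIMUNDA", "CICERA", "BENEDITA", "SEBASTIANA",
    "GERALDA", "CONCEICAO", "DAS", "GRACAS", "LOURDES", "SOCORRO", "PENHA",
    "NAZARE", "ROSANA", "ELZA", "ILDA", "NILZA", "WILMA", "ZELIA", "NORMA",
    "DORA", "EUNICE", "GENI", "HILDA", "IVANI", "JACIRA", "LEILA", "LIDIA",
    "LILIAN", "MAGDA", "NADIA", "OLGA", "ROSELI", "SALETE", "TANIA", "VILMA",
    "ZENAIDE", "ADELIA", "ALBERTINA", "ALZIRA", "AMELIA", "ANTONIETA",
    "AUGUSTA", "AURORA", "CARMELITA", "CAROLINA", "CATARINA", "CLEUSA",
    "CREUSA", "DEISE", "DENISE", "DIANA", "DULCE", "EDILEUZA", "EDITE",
    "ELENICE", "ELIETE", "ELISANGELA", "ELVIRA", "EMILIA", "ERICA", "EUGENIA",
    "EVA", "FABIANA", "FLAVIA", "FLORA", "FRANCELINA", "GILDA", "GISELE",
    "GLORIA", "GRAZIELA", "IEDA", "INES", "IONE", "ISAURA", "IVETE", "IZABEL",
    "JAQUELINE", "JOELMA", "JOSIANE", "JUCILENE", "JUREMA", "KATIA", "LAURINDA",
    "LEONOR", "LIGIA", "LINDALVA", "LUANA", "LUCILENE", "LUCIMAR", "MADALENA",
    "MANUELA", "MARILENE", "MARINA", "MARISA", "MARITA", "MIRIAM", "NEIDE",
    "NILDA", "NOEMI", "ONDINA", "PALMIRA", "QUITERIA", "ROSEMARY", "RUTE",
    "SELMA", "SILVANA", "SUELEN", "TEREZINHA", "URSULA", "VALDIRENE",
    "VALERIA", "WANDA", "ZULEIDE", "ADELAIDE", "AGATHA", "ALANA", "ALESSANDRA",
    "ANDREIA", "ARLETE", "BERNADETE", "BRIGIDA", "CINTIA", "CLARICE",
    "CLEIDE", "CRISTIANE", "DAIANE", "DAMIANA", "DARCI", "DEUSA", "DINA",
    "DOMINGAS", "EDILENE", "ELIANA", "EMANUELA", "FABIOLA", "FILOMENA",
    "GEORGINA", "GESSICA", "GIOVANA", "HORTENCIA", "IARA", "IRIS", "ITALIA",
    "IVANILDE", "JANAINA", "JANETE", "JOCELIA", "JUSSARA", "LAERCIA",
    "LEANDRA", "LUCELIA", "LUDMILA", "MAIARA", "MARCELA", "MAYARA", "MICHELI",
    "NICOLE", "NUBIA", "OLIVIA", "PAMELA", "PETRONILA", "POLIANA", "ROBERTA",
    "ROSILENE", "SAMARA", "SHEILA", "SUZANA", "TALITA", "VANUSA", "ZILMA",
)

# Given names used for generated children of either sex.
CHILD_NAMES: tuple[str, ...] = GIVEN_NAMES + (
    "JOSE", "JOAO", "PEDRO", "LUCAS", "GABRIEL", "MATHEUS", "RAFAEL", "DANIEL",
    "MARCOS", "PAULO", "CARLOS", "FELIPE", "BRUNO", "GUSTAVO", "EDUARDO",
    "ANDRE", "THIAGO", "LEONARDO", "VINICIUS", "RODRIGO", "FERNANDO",
    "ANTONIO", "FRANCISCO", "MIGUEL", "ARTHUR", "HEITOR", "BERNARDO", "DAVI",
    "THEO", "LORENZO", "BENJAMIN", "NICOLAS", "SAMUEL", "HENRIQUE", "MURILO",
    "CAIO", "ENZO", "ISAAC", "CAUA", "EMANUEL", "OTAVIO", "AUGUSTO", "LEVI",
    "YURI", "ALEXANDRE", "VITOR", "RAUL", "SERGIO", "RENATO", "CLAUDIO",
)

SURNAMES: tuple[str, ...] = (
    "SILVA", "SANTOS", "OLIVEIRA", "SOUZA", "RODRIGUES", "FERREIRA", "ALVES",
    "PEREIRA", "LIMA", "GOMES", "COSTA", "RIBEIRO", "MARTINS", "CARVALHO",
    "ALMEIDA", "LOPES", "SOARES", "FERNANDES", "VIEIRA", "BARBOSA", "ROCHA",
    "DIAS", "NASCIMENTO", "ANDRADE", "MOREIRA", "NUNES", "MARQUES", "MACHADO",
    "MENDES", "FREITAS", "CARDOSO", "RAMOS", "GONCALVES", "SANTANA", "TEIXEIRA",
    "ARAUJO", "BRITO", "CORREIA", "MIRANDA", "MONTEIRO", "CAVALCANTE",
    "MOURA", "BATISTA", "CAMPOS", "DUARTE", "MELO", "NOGUEIRA", "SALES",
    "CASTRO", "PINTO", "REIS", "AZEVEDO", "BORGES", "MAGALHAES", "MEDEIROS",
    "TAVARES", "AMORIM", "AGUIAR", "BARROS", "BEZERRA", "CUNHA", "DANTAS",
    "FARIAS", "FIGUEIREDO", "FONSECA", "GUIMARAES", "LACERDA", "LEAL", "LEITE",
    "MACEDO", "MAIA", "MORAES", "MOTA", "NEVES", "PAIVA", "PIRES", "QUEIROZ",
    "REZENDE", "SIQUEIRA", "VASCONCELOS", "XAVIER", "ABREU", "ANTUNES",
    "ASSIS", "BANDEIRA", "BARRETO", "BENTO", "BITTENCOURT", "BONFIM", "BRAGA",
    "BRANDAO", "BUENO", "CABRAL", "CALDAS", "CAMARA", "CAMARGO", "CANDIDO",
    "CAPISTRANO", "CARDOZO", "CARNEIRO", "CASSIANO", "CERQUEIRA", "CESAR",
    "CHAGAS", "CHAVES", "COELHO", "CONCEICAO", "CORDEIRO", "CORTES", "COUTINHO",
    "CRUZ", "CUSTODIO", "DOMINGUES", "DORNELES", "DUTRA", "ESPINDOLA",
    "ESTEVES", "EVANGELISTA", "FALCAO", "FEITOSA", "FELIX", "FIALHO", "FIRMINO",
    "FLORES", "FOGACA", "FONTES", "FRAGA", "FRANCA", "FRANCO", "FROTA",
    "FURTADO", "GALVAO", "GARCIA", "GASPAR", "GENTIL", "GERMANO", "GODOY",
    "GOUVEIA", "GRACA", "GUEDES", "GUERRA", "HOLANDA", "HONORATO", "JARDIM",
    "JESUS", "JUNQUEIRA", "LANDIM", "LARANJEIRA", "LEMOS", "LESSA", "LINHARES",
    "LISBOA", "LOBATO", "LOBO", "LOURENCO", "LUCENA", "LUZ", "MANSUR",
    "MARCELINO", "MARINHO", "MARIZ", "MATOS", "MAXIMO", "MELLO", "MENEZES",
    "MESQUITA", "MILAGRES", "MODESTO", "MONTES", "MORAIS", "MORENO", "MOURAO",
    "MUNIZ", "NASCENTE", "NAVARRO", "NERY", "NETO", "NOBREGA", "NOVAES",
    "OLIVA", "OTTONI", "PACHECO", "PADILHA", "PAES", "PANTOJA", "PASSOS",
    "PAZ", "PEDROSA", "PEIXOTO", "PENA", "PENHA", "PESSOA", "PIMENTA",
    "PIMENTEL", "PINHEIRO", "PONTES", "PORTO", "PRADO", "PRATES", "QUADROS",
    "QUINTANA", "RABELO", "RANGEL", "REGO", "RESENDE", "RIOS", "ROSA",
    "SALDANHA", "SALGADO", "SAMPAIO", "SARAIVA", "SARMENTO", "SEABRA",
    "SERPA", "SERRANO", "SEVERO", "SIMAO", "SIMOES", "SODRE", "SOUSA",
    "TELES", "TOLEDO", "TORRES", "TRINDADE", "VALENTE", "VALERIO", "VARGAS",
    "VAZ", "VELOSO", "VENTURA", "VERAS", "VERISSIMO", "VIANA", "VILELA",
    "VILLAR", "WANDERLEY", "ZAGO", "ZANETTI", "ZIMMERMANN",
)

CONNECTIVES: tuple[str, ...] = ("DA", "DE", "DO", "DAS", "DOS", "E")

#: Tokens that mark a recorded name as a placeholder rather than a person
#: (newborn markers, unknown/ignored flags, test entries).
DEFAULT_STOP_TERMS: frozenset[str] = frozenset(
    {
        "RN", "RECEM", "NASCIDO", "NASCIDA", "NATIMORTO", "NATIMORTA",
        "IGNORADO", "IGNORADA", "DESCONHECIDO", "DESCONHECIDA",
        "INDIGENTE", "FALECIDO", "FALECIDA", "TESTE", "XXX", "NULL",
    }
)


def default_lexicon() -> frozenset[str]:
    """All tokens considered plausible name components."""
    return frozenset(GIVEN_NAMES) | frozenset(CHILD_NAMES) | frozenset(SURNAMES) | frozenset(CONNECTIVES)
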