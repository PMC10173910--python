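# Plano de Gestão de Dados

- **Projeto:** $project_name
- **Número do projeto:** $project_number
- **Investigador(a) principal:** $principal_investigator
- **Financiamento:** $funding
- **Instituição:** $institution
- **Data de elaboração:** $prepared_on

## 1. Dados e recursos do estudo

Descrição dos dados coletados, instrumentos utilizados e recursos do
estudo "$project_name".

$data_description

## 2. Segurança e privacidade

Medidas de proteção, controle de acesso e anonimização aplicadas aos
dados do estudo.

$security_measures

## 3. Acesso e arquivamento dos dados

Formas de acesso, compartilhamento, preservação e arquivamento dos dados
após o término do estudo.

$access_and_archiving

## 4. Aspectos éticos e regulatórios

Aprovações éticas, consentimento e conformidade regulatória aplicáveis.

$ethical_aspects
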